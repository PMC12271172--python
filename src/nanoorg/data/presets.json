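{
  "vehicle": {
    "scaffold": {
      "mean_area_nm2": 130100.0,
      "loc_density_per_nm2": 0.004,
      "ssd_area_nm2": 5200.0,
      "n_ssd_range": [
        1,
        4
      ]
    },
    "receptor": {
      "mean_area_nm2": 50100.0,
      "loc_density_per_nm2": 0.0043,
      "ssd_area_nm2": 1134.0,
      "n_ssd_range": [
        1,
        3
      ]
    }
  },
  "dzp": {
    "scaffold": {
      "mean_area_nm2": 98900.0,
      "loc_density_per_nm2": 0.004,
      "ssd_area_nm2": 4200.0,
      "n_ssd_range": [
        1,
        4
      ]
    },
    "receptor": {
      "mean_area_nm2": 35400.0,
      "loc_density_per_nm2": 0.0065,
      "ssd_area_nm2": 1134.0,
      "n_ssd_range": [
        1,
        3
      ]
    }
  }
}
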