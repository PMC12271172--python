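import numpy as np
import pandas as pd
import pytest

from nanoorg import synth
from nanoorg.locio import LocalizationTable


def make_table(xy, frames=None, photons=None, precision=10.0, **kwargs):
    """LocalizationTable from a coordinate array, defaults filled in."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    n = len(xy)
    df = pd.DataFrame({
        "frame": np.zeros(n, dtype=int) if frames is None else np.asarray(frames),
        "x": xy[:, 0], "y": xy[:, 1],
        "photons": np.full(n, 1000.0) if photons is None else np.asarray(photons),
        "precision": np.full(n, float(precision)),
    })
    return LocalizationTable(df=df, **kwargs)


@pytest.fixture(scope="session")
def small_field():
    """A small seeded two-channel synthetic field shared across tests."""
    cfg = synth.config_from_preset("vehicle", seed=42, n_synapses=8,
                                   field_extent=(8000.0, 8000.0))
    receptor, scaffold, vgat_mask, truths = synth.generate_field(cfg)
    return {"cfg": cfg, "receptor": receptor, "scaffold": scaffold,
            "vgat_mask": vgat_mask, "truths": truths}
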