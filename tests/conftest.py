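import numpy as np
import pytest

from paleospd import (SimConfig, TaxonScenario, UncalDate, calibrate_date,
                      calibrate_specimens, load_specimens,
                      make_synthetic_curve, simulate_assemblage)


@pytest.fixture(scope="session")
def identity_curve():
    return make_synthetic_curve("identity", 0, 10000, 0.0)


@pytest.fixture(scope="session")
def wiggly_curve():
    return make_synthetic_curve("wiggly", 0, 12000, 10.0, seed=1)


@pytest.fixture
def write_curve(tmp_path):
    """Write a CalibrationCurve to a .14c-style file and return the path."""

    def _write(curve, name="curve.14c", header=True):
        path = tmp_path / name
        with open(path, "w") as fh:
            if header:
                fh.write("# calBP,14C age BP,1-sigma\n")
            for g, m, s in zip(curve.grid, curve.mu, curve.sigma_curve):
                fh.write(f"{g},{m:.4f},{s:.4f}\n")
        return path

    return _write


def write_specimens(path, rows):
    """rows: (specimen_id, site_id, taxon, c14_age, c14_error[, fraction])"""
    with open(path, "w") as fh:
        fh.write("specimen_id,site_id,taxon,c14_age,c14_error,fraction\n")
        for row in rows:
            frac = row[5] if len(row) > 5 else "unknown"
            fh.write(f"{row[0]},{row[1]},{row[2]},{row[3]},{row[4]},{frac}\n")
    return path


def two_taxon_null_assemblage(curve, seed, n=20, n_sites=6, window=(10000, 1)):
    """Two taxa, identical uniform deposition: the exchangeable null."""
    scenarios = tuple(
        TaxonScenario(taxon, window[0], window[1]) for taxon in ("A", "B"))
    cfg = SimConfig(scenarios=scenarios, n_per_taxon=n,
                    sites=tuple((f"cave-{i}", 1.0) for i in range(n_sites)),
                    curve=curve, seed=seed)
    return simulate_assemblage(cfg)


def records_from_frame(df, curve, tmp_path, level=0.954, name="spec.csv"):
    path = tmp_path / name
    df.to_csv(path, index=False)
    return calibrate_specimens(load_specimens(path), curve, level=level)
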