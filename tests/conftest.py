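import numpy as np
import pytest

from lipidff import ConformerRecord, FitDataset, TorsionSeries, TorsionTerm


@pytest.fixture
def simple_series() -> TorsionSeries:
    return TorsionSeries(
        [
            TorsionTerm(periodicity=1, barrier=1.2, phase=0.0),
            TorsionTerm(periodicity=2, barrier=0.4, phase=180.0),
            TorsionTerm(periodicity=3, barrier=0.9, phase=0.0),
        ],
        label="cD-cD-cD-cD",
    )


@pytest.fixture
def five_conformer_dataset() -> FitDataset:
    rng = np.random.default_rng(42)
    angles = rng.uniform(-180, 180, size=5)
    ez = rng.normal(0, 1, size=5)
    eq = rng.normal(0, 1, size=5)
    return FitDataset(
        conformers=[
            ConformerRecord(angles={"L": float(a)}, e_zeroed=float(z), e_qm=float(q))
            for a, z, q in zip(angles, ez, eq)
        ],
        fitted_labels=("L",),
    )


def curve_rmse(series_a: TorsionSeries, series_b: TorsionSeries) -> float:
    """Offset-aligned RMSE between two torsion energy curves on a 5-degree grid."""
    from lipidff import torsion_energy

    grid = np.arange(-175.0, 180.0 + 1e-9, 5.0)
    d = torsion_energy(series_a, grid) - torsion_energy(series_b, grid)
    d = d - d.mean()
    return float(np.sqrt(np.mean(d**2)))
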