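import numpy as np
import pytest

from turnoverkit import (
    PeptideObservation,
    PeptideSeries,
    SimulationSpec,
    TissueCoefficients,
    protein_fraction,
    rate_from_half_life,
    simulate_tissue,
)

STUDY_TIMEPOINTS = (3.0, 7.0, 14.0, 30.0, 60.0)
STUDY_REPLICATES = (5, 4, 4, 4, 5)


@pytest.fixture
def coeffs():
    """A solid-tissue coefficient triple used across the model tests."""
    return TissueCoefficients(k_st=0.25, k_bt=0.05, k_a0=0.10)


def make_series(
    coeffs: TissueCoefficients,
    half_life: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    timepoints=STUDY_TIMEPOINTS,
    replicates=STUDY_REPLICATES,
    sequence: str = "ACDEFGHIK",
    protein_id: str = "P1",
    total_intensity: float = 1e6,
) -> PeptideSeries:
    """Synthetic peptide series following the model at known parameters."""
    k = rate_from_half_life(half_life)
    obs = []
    for tp, n_rep in zip(timepoints, replicates):
        truth = float(protein_fraction(coeffs, k, tp))
        for rep in range(n_rep):
            ratio = truth
            if noise_sd > 0:
                assert rng is not None
                ratio = float(np.clip(truth + rng.standard_normal() * noise_sd, 0, 1))
            obs.append(
                PeptideObservation(
                    source_file=f"sim_x_{int(tp)}d_bio{rep + 1}.raw",
                    timepoint=float(tp),
                    light=ratio * total_intensity,
                    heavy=(1.0 - ratio) * total_intensity,
                )
            )
    return PeptideSeries(sequence, sequence, protein_id, obs)


@pytest.fixture
def small_tissue():
    """A small but complete synthetic experiment (fast to fit)."""
    spec = SimulationSpec(n_proteins=60, seed=11)
    return simulate_tissue(spec)
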