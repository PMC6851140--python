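import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dartsex as dx
from dartsex.calls import PaCall, SnpCall

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset_sim():
    """One study-scale simulation (zero noise, fixed preset seed)."""
    return dx.simulate(dx.study_preset())


@pytest.fixture(scope="session")
def preset_results(preset_sim):
    """Full pipeline fit on the study-scale simulation."""
    model = dx.SexLinkageModel(preset_sim.snp, preset_sim.pa, preset_sim.registry)
    return model.fit()


@pytest.fixture(scope="session")
def small_params():
    """A fast, reduced-size parameter set with the same planted structure."""
    return dx.SimParams(
        n_females=6,
        n_males1=4,
        n_males2=4,
        n_males3=3,
        n_unknown=2,
        n_perfect_loci=5,
        n_moderate_loci=20,
        n_pa_loci=3,
        n_autosomal_snp=300,
        n_autosomal_pa=300,
        seed=11,
    )


@pytest.fixture
def tiny_snp():
    """2 loci x 3 samples covering every SNP call category."""
    calls = np.array(
        [
            [SnpCall.HOM_REF, SnpCall.HET, SnpCall.NULL],
            [SnpCall.HOM_ALT, SnpCall.HOM_REF, SnpCall.HET],
        ],
        dtype=np.int8,
    )
    return dx.SnpMatrix(
        ["L1", "L2"],
        ["S1", "S2", "S3"],
        calls,
        ref_seq=["ACGT", "TTAA"],
        alt_seq=["ACTT", ""],
        call_rate=[1.0, 0.980769],
        reproducibility=[1.0, 1.0],
    )


@pytest.fixture
def tiny_pa():
    calls = np.array(
        [
            [PaCall.PRESENT, PaCall.ABSENT, PaCall.NULL],
            [PaCall.ABSENT, PaCall.ABSENT, PaCall.PRESENT],
        ],
        dtype=np.int8,
    )
    return dx.PresenceMatrix(
        ["P1", "P2"],
        ["S1", "S2", "S3"],
        calls,
        sequence=["TGCAG", ""],
        call_rate=[0.923077, 1.0],
        reproducibility=[1.0, 0.99],
    )


def snp_from_rows(rows, sexes, locus_ids=None):
    """Build an SnpMatrix from per-locus call lists plus a sex vector.

    Returns (matrix, registry); samples are named s0, s1, ...
    """
    rows = np.asarray(rows, dtype=np.int8)
    if rows.ndim == 1:
        rows = rows[None, :]
    n = rows.shape[1]
    samples = [f"s{i}" for i in range(n)]
    ids = locus_ids or [f"L{i}" for i in range(rows.shape[0])]
    registry = dx.SexRegistry(dict(zip(samples, sexes)))
    return dx.SnpMatrix(ids, samples, rows), registry
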