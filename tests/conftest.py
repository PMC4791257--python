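import pytest

from longclone.siminput import CloneSpec, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete simulated patient (fast to generate)."""
    config = SimConfig(
        seed=7,
        clones=[
            CloneSpec("trunk", 0.6, 0.85, n_segments=1, segment_length=15_000_000,
                      n_private_snvs=8),
            CloneSpec("emergent", None, 0.5, n_segments=1,
                      segment_length=15_000_000, n_private_snvs=8, parent="trunk"),
            CloneSpec("extinct", 0.3, None, n_segments=0, n_private_snvs=6,
                      parent="trunk"),
        ],
        n_germline_snps_per_mb=20.0,
        n_reference_segments=3,
        n_genes=200,
        n_deg_genes=10,
    )
    return simulate_cohort(config)


@pytest.fixture
def cohort_dir(small_cohort, tmp_path):
    small_cohort.write(tmp_path / "cohort")
    return tmp_path / "cohort"
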