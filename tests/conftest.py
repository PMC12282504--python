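import numpy as np
import pytest

from plscorr import AnalysisConfig, SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Small, fast cohort: 24 ED (16 EDr + 8 EDbp) + 8 HC, 6 x 5 blocks."""
    return SyntheticSpec(
        n_edr=16,
        n_edbp=8,
        n_hc=8,
        p=6,
        q=5,
        n_latent=1,
        effect_brain=(2.0,),
        effect_behavior=(2.0,),
        brain_support=3,
        behavior_support=3,
        subtype_shift=0.0,
        seed=7,
    )


@pytest.fixture
def small_dataset(small_spec):
    ds, gt = generate_dataset(small_spec)
    return ds, gt


@pytest.fixture
def fast_config():
    return AnalysisConfig(
        n_permutations=49,
        n_bootstraps=50,
        n_cv_splits=10,
        n_cv_null=0,
        seed=11,
    )


def write_csv(path, header, rows):
    lines = [",".join(header)]
    lines += [",".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def csv_trio(tmp_path):
    """Three aligned CSVs with 5 subjects, 3 ROIs, 2 behaviors."""
    sids = [f"s{i}" for i in range(1, 6)]
    rng = np.random.default_rng(0)
    brain = write_csv(
        tmp_path / "brain.csv",
        ["subject_id", "roiA", "roiB", "roiC"],
        [[s, *np.round(rng.normal(size=3), 6)] for s in sids],
    )
    behavior = write_csv(
        tmp_path / "behavior.csv",
        ["subject_id", "b1", "b2"],
        [[s, *np.round(rng.normal(size=2), 6)] for s in sids],
    )
    meta = write_csv(
        tmp_path / "metadata.csv",
        ["subject_id", "age", "group", "subtype", "ede_baseline", "ede_followup"],
        [
            ["s1", 15.2, "ED", "EDr", 3.1, 2.0],
            ["s2", 16.0, "ED", "EDbp", 4.0, ""],
            ["s3", 14.8, "HC", "", 0.2, ""],
            ["s4", 17.1, "ED", "EDr", 2.5, 1.1],
            ["s5", 13.9, "HC", "", 0.1, ""],
        ],
    )
    return brain, behavior, meta
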