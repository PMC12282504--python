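"""Shared data model and delimited-text I/O.

A study dataset couples a brain matrix (one column per ROI), a behavior
matrix (one column per measure), and subject metadata (age, group, diagnostic
subtype, baseline and follow-up severity) under a single subject ordering.
All files are comma-separated UTF-8 text with a header row; the first column
is always ``subject_id``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LEVELS = ("ED", "HC")
SUBTYPE_LEVELS = ("EDr", "EDbp")
BEHAVIOR_DOMAINS = ("cognition", "temperament", "interoception", "emotion", "ed_symptoms")

#: fixed text format for numeric tables; 12+ significant digits guarantees
#: float round-trip while keeping outputs byte-stable across reruns
FLOAT_FORMAT = "%.17g"

META_COLUMNS = ("subject_id", "age", "group", "subtype", "ede_baseline", "ede_followup")


class DatasetError(ValueError):
    """Raised for malformed or inconsistent study input files."""


@dataclass(frozen=True)
class ValidationFinding:
    """One issue reported by :func:`validate_dataset`."""

    level: str  # "warning" or "failure"
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.message}"


@dataclass
class StudyDataset:
    """Aligned subject-level brain block, behavior block, and metadata."""

    subject_id: np.ndarray  # (n,) str
    brain: np.ndarray  # (n, p) float
    behavior: np.ndarray  # (n, q) float
    age: np.ndarray  # (n,) float, years
    group: np.ndarray  # (n,) str in {"ED", "HC"}
    subtype: np.ndarray  # (n,) str in {"EDr", "EDbp", "NA"}
    baseline_severity: np.ndarray  # (n,) float, EDE global 0-6
    followup_severity: np.ndarray  # (n,) float, NaN where missing
    roi_names: list[str]
    behavior_names: list[str]
    behavior_domains: list[str]

    @property
    def n(self) -> int:
        return len(self.subject_id)

    @property
    def p(self) -> int:
        return self.brain.shape[1]

    @property
    def q(self) -> int:
        return self.behavior.shape[1]

    def subset(self, mask: np.ndarray) -> "StudyDataset":
        """Return a new dataset restricted to ``mask`` (bool or index array)."""
        mask = np.asarray(mask)
        return StudyDataset(
            subject_id=self.subject_id[mask],
            brain=self.brain[mask],
            behavior=self.behavior[mask],
            age=self.age[mask],
            group=self.group[mask],
            subtype=self.subtype[mask],
            baseline_severity=self.baseline_severity[mask],
            followup_severity=self.followup_severity[mask],
            roi_names=list(self.roi_names),
            behavior_names=list(self.behavior_names),
            behavior_domains=list(self.behavior_domains),
        )

    def ed_subset(self) -> "StudyDataset":
        return self.subset(self.group == "ED")

    def equals(self, other: "StudyDataset", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Exact (or toleranced) equality of all fields, NaN-aware."""
        if (
            list(self.subject_id) != list(other.subject_id)
            or self.roi_names != other.roi_names
            or self.behavior_names != other.behavior_names
            or self.behavior_domains != other.behavior_domains
            or list(self.group) != list(other.group)
            or list(self.subtype) != list(other.subtype)
        ):
            return False
        for a, b in (
            (self.brain, other.brain),
            (self.behavior, other.behavior),
            (self.age, other.age),
            (self.baseline_severity, other.baseline_severity),
            (self.followup_severity, other.followup_severity),
        ):
            if a.shape != b.shape:
                return False
            if not np.allclose(a, b, rtol=rtol, atol=atol, equal_nan=True):
                return False
        return True


@dataclass
class AnalysisConfig:
    """Tuning knobs for the inference stages.

    Defaults mirror the study design where stated (100 cross-validation
    splits of 75% train / 25% test, bootstrap-ratio threshold 1.96) and
    conventional behavioral-PLS practice elsewhere.
    """

    n_permutations: int = 10_000
    n_bootstraps: int = 5_000
    n_cv_splits: int = 100
    train_fraction: float = 0.75
    alpha: float = 0.05
    bsr_threshold: float = 1.96
    seed: int = 0
    imaging_modality_label: str = "RND"
    # --- extras -----------------------------------------------------------
    analysis_group: str = "ED"  # "ED", "HC", or "all"
    age_correct: bool = True  # age-residualize the brain block
    stratify_cv: bool = True
    n_cv_null: int = 500  # permutation repetitions for the CV p-value; 0 skips
    rotate_permutation: bool = False  # see inference.permutation_test
    bootstrap_align: str = "signed_permutation"  # or "rotation"; see inference
    meff_method: str = "eigenvalue_variance"

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("n_permutations", "n_bootstraps", "n_cv_splits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "subject_id":
        raise DatasetError(f"{path.name}: first column must be 'subject_id', got {df.columns[0]!r}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise DatasetError(f"{path.name}: duplicated subject_id {sorted(set(dup))}")
    return df.set_index("subject_id")


def _coerce_numeric(df: pd.DataFrame, fname: str) -> pd.DataFrame:
    """Coerce all columns to float, reporting the coordinates of bad cells."""
    out = {}
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        # empty strings / NA markers already became NaN in read_csv
        if bad.any():
            sid = bad.idxmax()
            raise DatasetError(
                f"{fname}: non-numeric value {df[col][sid]!r} at subject "
                f"{sid!r}, column {col!r}"
            )
        out[col] = coerced.astype(float)
    return pd.DataFrame(out, index=df.index)


def read_dataset(
    brain_path: str | Path,
    behavior_path: str | Path,
    meta_path: str | Path,
    *,
    behavior_domains: Sequence[str] | None = None,
    strict: bool = True,
) -> StudyDataset:
    """Read and align the three study input files.

    Subjects are matched on ``subject_id`` and returned in sorted order.
    With ``strict=True`` (default) any subject that is not present in all
    three files is an error naming the offending ids; with ``strict=False``
    the intersection is taken with a logged warning. Subjects with missing
    brain, behavior, age, or group values are dropped (complete-case) and
    logged; follow-up severity may be missing.

    ``behavior_domains`` assigns a domain label per behavior column; if the
    behavior file carries a ``#domains`` comment row it is ignored — domains
    are plumbing for reporting only and default to ``"unknown"``.
    """
    brain = _read_table(brain_path)
    behavior = _read_table(behavior_path)
    meta = _read_table(meta_path)

    missing_meta = [c for c in META_COLUMNS[1:] if c not in meta.columns]
    if missing_meta:
        raise DatasetError(f"{Path(meta_path).name}: missing metadata columns {missing_meta}")

    rosters = {
        Path(brain_path).name: set(brain.index),
        Path(behavior_path).name: set(behavior.index),
        Path(meta_path).name: set(meta.index),
    }
    common = set.intersection(*rosters.values())
    extra = {fn: sorted(ids - common) for fn, ids in rosters.items() if ids - common}
    if extra:
        if strict:
            parts = "; ".join(f"{fn}: {ids}" for fn, ids in extra.items())
            raise DatasetError(f"subjects not present in all files — {parts}")
        logger.warning("dropping subjects not present in all files: %s", extra)

    order = sorted(common)
    brain = _coerce_numeric(brain.loc[order], Path(brain_path).name)
    behavior = _coerce_numeric(behavior.loc[order], Path(behavior_path).name)
    meta = meta.loc[order]

    age = pd.to_numeric(meta["age"], errors="coerce")
    group = meta["group"].astype(str)
    subtype = meta["subtype"].where(meta["subtype"].notna(), "NA").astype(str)
    base = pd.to_numeric(meta["ede_baseline"], errors="coerce")
    follow = pd.to_numeric(meta["ede_followup"], errors="coerce")

    bad_group = ~group.isin(GROUP_LEVELS)
    if bad_group.any():
        raise DatasetError(
            f"{Path(meta_path).name}: invalid group value(s) "
            f"{sorted(group[bad_group].unique())} (expected {list(GROUP_LEVELS)})"
        )
    bad_sub = ~subtype.isin(SUBTYPE_LEVELS + ("NA",))
    if bad_sub.any():
        raise DatasetError(
            f"{Path(meta_path).name}: invalid subtype value(s) {sorted(subtype[bad_sub].unique())}"
        )

    complete = (
        brain.notna().all(axis=1)
        & behavior.notna().all(axis=1)
        & age.notna()
    )
    if not complete.all():
        dropped = [sid for sid, ok in complete.items() if not ok]
        logger.warning("complete-case exclusion of %d subject(s): %s", len(dropped), dropped)
    keep = complete[complete].index

    if behavior_domains is None:
        behavior_domains = ["unknown"] * behavior.shape[1]
    if len(behavior_domains) != behavior.shape[1]:
        raise DatasetError("behavior_domains length must equal number of behavior columns")

    ds = StudyDataset(
        subject_id=np.asarray(keep, dtype=object),
        brain=brain.loc[keep].to_numpy(float),
        behavior=behavior.loc[keep].to_numpy(float),
        age=age.loc[keep].to_numpy(float),
        group=group.loc[keep].to_numpy(object),
        subtype=subtype.loc[keep].to_numpy(object),
        baseline_severity=base.loc[keep].to_numpy(float),
        followup_severity=follow.loc[keep].to_numpy(float),
        roi_names=list(brain.columns),
        behavior_names=list(behavior.columns),
        behavior_domains=list(behavior_domains),
    )
    failures = [f for f in validate_dataset(ds) if f.level == "failure"]
    if failures:
        raise DatasetError("; ".join(f.message for f in failures))
    return ds


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_dataset(ds: StudyDataset) -> list[ValidationFinding]:
    """Check invariants (hard failures) and data-quality heuristics (warnings).

    Pure function: never mutates or raises for data problems; callers decide
    what to do with the findings.
    """
    findings: list[ValidationFinding] = []
    fail = lambda msg: findings.append(ValidationFinding("failure", msg))  # noqa: E731
    warn = lambda msg: findings.append(ValidationFinding("warning", msg))  # noqa: E731

    n = len(ds.subject_id)
    for name, arr in (
        ("brain", ds.brain),
        ("behavior", ds.behavior),
        ("age", ds.age),
        ("group", ds.group),
        ("subtype", ds.subtype),
        ("baseline_severity", ds.baseline_severity),
        ("followup_severity", ds.followup_severity),
    ):
        if arr.shape[0] != n:
            fail(f"subject misalignment: {name} has {arr.shape[0]} rows, expected {n}")

    ids = list(ds.subject_id)
    if len(set(ids)) != len(ids):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        fail(f"duplicated subject_id: {dup}")
    if ds.brain.ndim != 2 or ds.brain.shape[1] < 2:
        fail("brain block must have p >= 2 columns")
    if ds.behavior.ndim != 2 or ds.behavior.shape[1] < 2:
        fail("behavior block must have q >= 2 columns")
    if len(ds.roi_names) != ds.brain.shape[1]:
        fail("roi_names length does not match brain columns")
    if len(ds.behavior_names) != ds.behavior.shape[1]:
        fail("behavior_names length does not match behavior columns")
    if len(ds.behavior_domains) != ds.behavior.shape[1]:
        fail("behavior_domains length does not match behavior columns")

    if ds.age.shape[0] == n and np.any(~(ds.age > 0)):
        bad = [ids[i] for i in np.nonzero(~(ds.age > 0))[0]]
        fail(f"non-positive age for subject(s) {bad}")
    if ds.group.shape[0] == n and ds.subtype.shape[0] == n:
        misplaced = (ds.group != "ED") & (ds.subtype != "NA")
        if misplaced.any():
            bad = [ids[i] for i in np.nonzero(misplaced)[0]]
            fail(f"subtype set for non-ED subject(s) {bad}")

    # warnings -------------------------------------------------------------
    for block, names in (("brain", ds.roi_names), ("behavior", ds.behavior_names)):
        arr = getattr(ds, block if block != "brain" else "brain")
        if arr.shape[0] != n or arr.ndim != 2:
            continue
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(arr, axis=0, ddof=1)
            scale = np.maximum(np.abs(np.nanmean(arr, axis=0)), 1.0)
        for j in np.nonzero(sd <= 1e-12 * scale)[0]:
            warn(f"zero-variance column {names[j]!r} in {block} block")
        miss = np.isnan(arr).mean(axis=0)
        for j in np.nonzero(miss > 0)[0]:
            warn(f"{block} column {names[j]!r}: {miss[j]:.1%} missing")
        if n >= 8:
            import warnings as _warnings

            from scipy import stats

            with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                skew = stats.skew(arr, axis=0, nan_policy="omit")
            for j in np.nonzero(np.abs(np.asarray(skew)) > 2)[0]:
                warn(f"{block} column {names[j]!r}: |skew| = {abs(skew[j]):.2f} > 2")
    return findings


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_dataset(ds: StudyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three study CSVs; returns {"brain":…, "behavior":…, "meta":…}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "brain": out / "brain.csv",
        "behavior": out / "behavior.csv",
        "meta": out / "metadata.csv",
    }
    pd.DataFrame(ds.brain, index=pd.Index(ds.subject_id, name="subject_id"), columns=ds.roi_names).to_csv(
        paths["brain"], float_format=FLOAT_FORMAT
    )
    pd.DataFrame(
        ds.behavior, index=pd.Index(ds.subject_id, name="subject_id"), columns=ds.behavior_names
    ).to_csv(paths["behavior"], float_format=FLOAT_FORMAT)
    meta = pd.DataFrame(
        {
            "age": ds.age,
            "group": ds.group,
            "subtype": pd.Series(ds.subtype).replace("NA", np.nan).to_numpy(),
            "ede_baseline": ds.baseline_severity,
            "ede_followup": ds.followup_severity,
        },
        index=pd.Index(ds.subject_id, name="subject_id"),
    )
    meta.to_csv(paths["meta"], float_format=FLOAT_FORMAT)
    return paths


def _frame(data: np.ndarray, index: Iterable[str], prefix: str) -> pd.DataFrame:
    data = np.atleast_2d(np.asarray(data))
    cols = [f"{prefix}{i + 1}" for i in range(data.shape[1])]
    return pd.DataFrame(data, index=pd.Index(index), columns=cols)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    out_dir: str | Path,
    *,
    decomposition,
    dataset: StudyDataset | None = None,
    inference=None,
    group_stats=None,
    config: AnalysisConfig | None = None,
) -> list[Path]:
    """Write result tables and a run summary; returns the list of files.

    Always writes weights, loadings, singular values, and subject scores.
    Inference and group-statistics tables are written when provided.
    """
    from . import __version__

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:  # pragma: no cover - OS dependent
        raise IOError(f"output directory not writable: {out}") from exc

    dec = decomposition
    k = dec.S.shape[0]
    roi = dec.roi_names if getattr(dec, "roi_names", None) else [f"roi{i+1}" for i in range(dec.U.shape[0])]
    beh = (
        dec.behavior_names
        if getattr(dec, "behavior_names", None)
        else [f"beh{i+1}" for i in range(dec.V.shape[0])]
    )
    subjects = dataset.subject_id if dataset is not None else np.arange(dec.brain_scores.shape[0])

    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, float_format=FLOAT_FORMAT)
        written.append(path)

    emit(
        "singular_values.csv",
        pd.DataFrame(
            {"singular_value": dec.S, "covariance_explained": dec.covexp},
            index=pd.Index([f"LV{i+1}" for i in range(k)], name="lv"),
        ),
    )
    emit("brain_weights.csv", _frame(dec.U, roi, "LV").rename_axis("roi"))
    emit("behavior_weights.csv", _frame(dec.V, beh, "LV").rename_axis("measure"))
    emit("brain_loadings.csv", _frame(dec.brain_loadings, roi, "LV").rename_axis("roi"))
    emit("behavior_loadings.csv", _frame(dec.behavior_loadings, beh, "LV").rename_axis("measure"))

    scores = pd.concat(
        [
            _frame(dec.brain_scores, subjects, "brain_LV"),
            _frame(dec.behavior_scores, subjects, "behavior_LV"),
        ],
        axis=1,
    ).rename_axis("subject_id")
    emit("subject_scores.csv", scores)

    if inference is not None:
        emit(
            "permutation.csv",
            pd.DataFrame(
                {
                    "singular_value": dec.S,
                    "perm_pvalue": inference.perm_pvalues,
                    "significant": inference.perm_pvalues
                    < (config.alpha if config else 0.05),
                },
                index=pd.Index([f"LV{i+1}" for i in range(k)], name="lv"),
            ),
        )
        emit(
            "brain_bootstrap.csv",
            pd.concat(
                [
                    _frame(inference.bootstrap_ratios_brain, roi, "bsr_LV"),
                    _frame(inference.bootstrap_se_brain, roi, "se_LV"),
                    _frame(inference.brain_loading_lower, roi, "load_lo_LV"),
                    _frame(inference.brain_loading_upper, roi, "load_hi_LV"),
                ],
                axis=1,
            ).rename_axis("roi"),
        )
        emit(
            "behavior_bootstrap.csv",
            pd.concat(
                [
                    _frame(inference.bootstrap_ratios_behavior, beh, "bsr_LV"),
                    _frame(inference.bootstrap_se_behavior, beh, "se_LV"),
                    _frame(inference.behavior_loading_lower, beh, "load_lo_LV"),
                    _frame(inference.behavior_loading_upper, beh, "load_hi_LV"),
                ],
                axis=1,
            ).rename_axis("measure"),
        )
        if inference.cv_split_rs is not None:
            emit(
                "cv_splits.csv",
                pd.DataFrame(
                    inference.cv_split_rs,
                    index=pd.Index(range(1, inference.cv_split_rs.shape[0] + 1), name="split"),
                    columns=[f"LV{lv+1}" for lv in inference.cv_lvs],
                ),
            )
            cv_rows = {
                "mean_out_of_sample_r": inference.cv_out_of_sample_r,
            }
            if inference.cv_pvalues is not None:
                cv_rows["cv_pvalue"] = inference.cv_pvalues
            emit(
                "cv_summary.csv",
                pd.DataFrame(cv_rows, index=pd.Index([f"LV{lv+1}" for lv in inference.cv_lvs], name="lv")),
            )

    if group_stats is not None:
        emit("group_descriptives.csv", group_stats.table)

    summary = out / "run_summary.txt"
    lines = [f"plscorr_version: {__version__}"]
    if config is not None:
        for key, value in sorted(config.to_dict().items()):
            lines.append(f"config.{key}: {value}")
    lines.append(f"n_latent_variables: {k}")
    if dataset is not None:
        lines.append(f"n_subjects: {dataset.n}")
        lines.append(f"n_brain_columns: {dataset.p}")
        lines.append(f"n_behavior_columns: {dataset.q}")
    lines.append(f"files: {', '.join(p.name for p in written)}")
    summary.write_text("\n".join(lines) + "\n", encoding="utf-8")
    written.append(summary)
    return written
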