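"""End-to-end pipeline: normalize, decompose, resample, report.

``run_pipeline`` chains the stages on one dataset and writes every result
table plus a JSON manifest; ``render_report`` turns a results directory into
a human-readable markdown summary.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical
from .datamodel import (
    AnalysisConfig,
    StudyDataset,
    file_sha256,
    read_dataset,
    validate_dataset,
    write_results,
)
from .decomposition import decompose, score_correlation
from .inference import run_inference
from .preprocess import cross_correlation, effective_rank, fit_preprocess

import logging

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_hashes: dict[str, str]
    timings: dict[str, float]
    outputs: list[str]
    version: str
    n_subjects: int
    n_significant_lvs: int
    meff_brain: float | None = None
    meff_behavior: float | None = None

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")
        return path


class PipelineError(RuntimeError):
    pass


def _stage(name: str, timings: dict[str, float]):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = time.perf_counter() - self.t0
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return _Ctx()


def run_pipeline(
    brain_path: str | Path,
    behavior_path: str | Path,
    meta_path: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | str | Path | None = None,
) -> RunManifest:
    """Execute the full analysis and write all result tables.

    The analysis sample is selected by ``config.analysis_group`` (``"ED"``
    by default, matching the primary run; ``"HC"`` or ``"all"`` re-run the
    identical pipeline on alternative samples, and swapping the brain file
    re-runs it on an alternative imaging modality).
    """
    if config is None:
        config = AnalysisConfig()
    elif not isinstance(config, AnalysisConfig):
        config = AnalysisConfig.from_yaml(config)

    out_dir = Path(out_dir)
    timings: dict[str, float] = {}
    from . import __version__

    with _stage("read", timings):
        ds_full = read_dataset(brain_path, behavior_path, meta_path)
        for finding in validate_dataset(ds_full):
            logger.warning("%s", finding)
        if config.analysis_group == "all":
            ds = ds_full
        else:
            ds = ds_full.subset(ds_full.group == config.analysis_group)
        if ds.n < 3:
            raise ValueError(f"analysis sample {config.analysis_group!r} has n = {ds.n}")

    with _stage("preprocess", timings):
        Zx, Zy, model = fit_preprocess(ds)
        R = cross_correlation(Zx, Zy)
        meff_x, _ = effective_rank(np.corrcoef(Zx, rowvar=False), config.meff_method)
        meff_y, _ = effective_rank(np.corrcoef(Zy, rowvar=False), config.meff_method)

    with _stage("decompose", timings):
        dec = decompose(R, Zx, Zy, roi_names=ds.roi_names, behavior_names=ds.behavior_names)

    with _stage("inference", timings):
        inf = run_inference(ds, dec, config)
        n_sig = int(np.sum(inf.perm_pvalues < config.alpha))

    with _stage("clinical", timings):
        stats_table = clinical.group_descriptives(ds_full, list(ds_full.behavior_names))
        extra_tables: dict[str, pd.DataFrame] = {}
        sig_lvs = [int(i) for i in np.nonzero(inf.perm_pvalues < config.alpha)[0]] or [0]
        has_subtypes = (
            np.sum(ds.subtype == "EDr") >= 3 and np.sum(ds.subtype == "EDbp") >= 3
        )
        if has_subtypes:
            sub = clinical.compare_subtypes(ds, dec, lvs=sig_lvs)
            extra_tables["subtype_comparison.csv"] = sub.table
            extra_tables["within_subtype_correlations.csv"] = sub.within_correlations
        n_follow = int(np.sum(~np.isnan(ds.followup_severity) & ~np.isnan(ds.baseline_severity)))
        if n_follow >= 10:
            rows = []
            for lv in sig_lvs:
                for score_type in ("brain", "behavior"):
                    pc = clinical.prospective_association(ds, dec, lv, score_type)
                    rows.append(
                        {"lv": lv + 1, "score_type": score_type, "partial_r": pc.r, "p": pc.p, "n": pc.n}
                    )
            extra_tables["prospective.csv"] = pd.DataFrame(rows)
        score_rows = []
        for lv in sig_lvs:
            r, p = score_correlation(dec.brain_scores[:, lv], dec.behavior_scores[:, lv])
            score_rows.append({"lv": lv + 1, "in_sample_r": r, "p": p})
        extra_tables["score_correlations.csv"] = pd.DataFrame(score_rows)

    with _stage("write", timings):
        written = write_results(
            out_dir,
            decomposition=dec,
            dataset=ds,
            inference=inf,
            group_stats=stats_table,
            config=config,
        )
        from .datamodel import FLOAT_FORMAT

        for name, df in extra_tables.items():
            path = out_dir / name
            df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
            written.append(path)

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        input_hashes={
            "brain": file_sha256(brain_path),
            "behavior": file_sha256(behavior_path),
            "meta": file_sha256(meta_path),
        },
        timings=timings,
        outputs=[p.name for p in written],
        version=__version__,
        n_subjects=ds.n,
        n_significant_lvs=n_sig,
        meff_brain=meff_x,
        meff_behavior=meff_y,
    )
    manifest.write(out_dir / "manifest.json")
    for name in manifest.outputs:
        assert (out_dir / name).exists()
    return manifest


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def _read_threshold(results_dir: Path) -> float:
    summary = results_dir / "run_summary.txt"
    if summary.exists():
        for line in summary.read_text().splitlines():
            if line.startswith("config.bsr_threshold:"):
                return float(line.split(":", 1)[1])
    return 1.96


def render_report(results_dir: str | Path, top: int = 15) -> str:
    """Render a markdown report from a results directory.

    Emits per-LV loading and bootstrap-ratio tables sorted by absolute
    magnitude and flagged at the configured thresholds. Works with
    decomposition-only results (with a warning); errors if the core
    decomposition tables are missing.
    """
    results_dir = Path(results_dir)
    required = ["singular_values.csv", "brain_loadings.csv", "behavior_loadings.csv"]
    missing = [f for f in required if not (results_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing result tables: {missing}")

    sv = pd.read_csv(results_dir / "singular_values.csv", index_col=0)
    threshold = _read_threshold(results_dir)
    lines = ["# PLS analysis report", ""]

    perm_path = results_dir / "permutation.csv"
    have_inference = perm_path.exists()
    if have_inference:
        perm = pd.read_csv(perm_path, index_col=0)
        sv = sv.join(perm[["perm_pvalue", "significant"]])
    else:
        lines.append("> **Warning:** no inference tables found; decomposition-only report.")
        lines.append("")

    lines.append("## Latent variables")
    lines.append("")
    lines.append(sv.head(10).to_markdown(floatfmt=".4f"))
    lines.append("")

    n_lvs = int(sv["significant"].sum()) if have_inference else min(2, len(sv))
    n_lvs = max(n_lvs, 1)

    behavior_loadings = pd.read_csv(results_dir / "behavior_loadings.csv", index_col=0)
    boot_path = results_dir / "behavior_bootstrap.csv"
    behavior_boot = pd.read_csv(boot_path, index_col=0) if boot_path.exists() else None
    brain_boot_path = results_dir / "brain_bootstrap.csv"
    brain_boot = pd.read_csv(brain_boot_path, index_col=0) if brain_boot_path.exists() else None

    for lv in range(1, n_lvs + 1):
        lines.append(f"## LV-{lv}")
        lines.append("")
        col = f"LV{lv}"
        table = behavior_loadings[[col]].rename(columns={col: "loading"})
        if behavior_boot is not None:
            table["ci_lower"] = behavior_boot[f"load_lo_LV{lv}"]
            table["ci_upper"] = behavior_boot[f"load_hi_LV{lv}"]
            table["reliable"] = (table["ci_lower"] > 0) | (table["ci_upper"] < 0)
        table = table.reindex(table["loading"].abs().sort_values(ascending=False).index)
        lines.append(f"### Behavior loadings (top {top} by |loading|)")
        lines.append("")
        lines.append(table.head(top).to_markdown(floatfmt=".4f"))
        lines.append("")
        if brain_boot is not None:
            bsr = brain_boot[[f"bsr_LV{lv}"]].rename(columns={f"bsr_LV{lv}": "bootstrap_ratio"})
            bsr["reliable"] = bsr["bootstrap_ratio"].abs() > threshold
            bsr = bsr.reindex(bsr["bootstrap_ratio"].abs().sort_values(ascending=False).index)
            lines.append(f"### Brain bootstrap ratios (top {top}, threshold |{threshold}|)")
            lines.append("")
            lines.append(bsr.head(top).to_markdown(floatfmt=".4f"))
            lines.append("")

    for extra in ("score_correlations.csv", "cv_summary.csv", "subtype_comparison.csv", "prospective.csv"):
        path = results_dir / extra
        if path.exists():
            lines.append(f"## {extra.removesuffix('.csv').replace('_', ' ').capitalize()}")
            lines.append("")
            lines.append(pd.read_csv(path).to_markdown(index=False, floatfmt=".4f"))
            lines.append("")

    text = "\n".join(lines)
    (results_dir / "report.md").write_text(text, encoding="utf-8")
    return text
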