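"""End-to-end orchestration: imaging chain, analysis battery, demo.

``run_imaging`` chains tensor fit → diffusivity maps → ALPS index → PVS
volumetry per subject-visit with per-subject failure isolation.
``run_analysis`` runs the statistical battery over a long-format cohort
table in the order baseline associations → progression → cognition →
dementia, with BH-FDR applied within each results table, plus cutpoint
survival stratification and variable importance.  ``end_to_end_demo``
wires the synthetic generators through both stages and renders a
markdown report.

Everything is deterministic given the config seed; outputs are
regenerable bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pvsalps.acquisition import DiffusionAcquisition, load_dwi
from pvsalps.alps import build_roi_set, compute_alps
from pvsalps.cohort import CohortSpec, generate_cohort
from pvsalps.phantoms import generate_alps_phantom, generate_tissue_phantom
from pvsalps.pvs import TissueMaps, make_pvs_map, pvs_volumes
from pvsalps.stats import (
    ModelSpec,
    best_cutpoint,
    fdr_adjust,
    fit_cox,
    fit_linear,
    fit_lmm,
    fit_logistic,
    km_logrank,
    variable_importance,
)
from pvsalps.tensor import derive_maps, fit_tensor, median_md, psmd

__all__ = [
    "RunConfig",
    "SubjectVisit",
    "run_imaging",
    "run_analysis",
    "end_to_end_demo",
]

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "n_subjects",
    "fast",
    "roi_centers",
    "roi_diameter",
    "signal_floor_rel",
    "orientation_threshold",
    "fdr_families",
    "verbosity",
}


@dataclass
class RunConfig:
    """Run-wide options; unknown YAML keys are rejected at load time."""

    seed: int = 0
    out_dir: str | None = None
    n_subjects: int = 120
    fast: bool = False
    roi_centers: list | None = None
    roi_diameter: float = 6.0
    signal_floor_rel: float = 1e-6
    orientation_threshold: float = 0.5
    fdr_families: str = "per_table"
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def roi_set(self):
        if self.roi_centers is None:
            return build_roi_set(diameter=self.roi_diameter)
        centers = tuple(tuple(float(x) for x in c) for c in self.roi_centers)
        return build_roi_set(centers, diameter=self.roi_diameter)


@dataclass
class SubjectVisit:
    """Inputs for one subject-visit of the imaging chain.

    Either in-memory objects (``acquisition``, ``tissue``) or file paths
    (``dwi``/``bval``/``bvec`` NIfTI + FSL text) may be supplied.
    """

    subject_id: str
    visit_year: float = 0.0
    acquisition: DiffusionAcquisition | None = None
    tissue: TissueMaps | None = None
    dwi: str | None = None
    bval: str | None = None
    bvec: str | None = None
    mask: str | None = None
    map_to_template: np.ndarray = field(default_factory=lambda: np.eye(4))
    wm_skeleton: np.ndarray | None = None

    def load_acquisition(self) -> DiffusionAcquisition:
        if self.acquisition is not None:
            return self.acquisition
        if self.dwi is None or self.bval is None or self.bvec is None:
            raise ValueError(
                f"{self.subject_id}: no acquisition and incomplete DWI paths"
            )
        for p in (self.dwi, self.bval, self.bvec):
            if not Path(p).exists():
                raise FileNotFoundError(f"{self.subject_id}: missing input {p}")
        return load_dwi(self.dwi, self.bval, self.bvec, self.mask)


def run_imaging(
    subject_visits: list[SubjectVisit],
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-subject-visit imaging markers with failure isolation.

    Returns one row per successful subject-visit (ALPS left/right/mean,
    PVS volumes raw/normalized/log per region, median MD, PSMD, QC
    counts) and a list of per-subject failure records.  Deterministic
    given identical inputs.
    """
    if config is None:
        config = RunConfig()
    rois = config.roi_set()
    rows: list[dict] = []
    failures: list[dict] = []
    for sv in subject_visits:
        try:
            acq = sv.load_acquisition()
            tensors = fit_tensor(acq, signal_floor_rel=config.signal_floor_rel)
            maps = derive_maps(tensors)
            alps = compute_alps(
                maps,
                rois,
                map_to_template=sv.map_to_template,
                orientation_threshold=config.orientation_threshold,
            )
            row = {
                "subject_id": sv.subject_id,
                "visit_year": sv.visit_year,
                "alps_left": alps.left,
                "alps_right": alps.right,
                "alps_mean": alps.mean,
                "n_invalid_roi_voxels": sum(
                    q.get("n_invalid", 0) for q in alps.qc.values()
                ),
                "orientation_warn": any(
                    q.get("orientation_warn", False) for q in alps.qc.values()
                ),
            }
            if sv.tissue is not None:
                t = sv.tissue
                pvs_map = make_pvs_map(t)
                has_pvs = bool(pvs_map.any())
                vols = pvs_volumes(pvs_map, t, log=has_pvs)
                row.update({f"pvs_{k}": v for k, v in vols.to_dict().items()})
                row["md_median"] = median_md(maps, _resample_mask(t.wm, maps.shape))
                skel = (
                    sv.wm_skeleton
                    if sv.wm_skeleton is not None
                    else _resample_mask(t.wm, maps.shape)
                )
                row["psmd"] = psmd(maps, skel)
            rows.append(row)
        except Exception as exc:
            failures.append({"subject_id": sv.subject_id, "error": str(exc)})
    return pd.DataFrame(rows), failures


def _resample_mask(mask: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Nearest-neighbour resample of a binary mask onto a target grid."""
    mask = np.asarray(mask)
    if mask.shape == shape:
        return mask
    idx = [
        np.clip(
            np.round(np.linspace(0, mask.shape[a] - 1, shape[a])).astype(int),
            0,
            mask.shape[a] - 1,
        )
        for a in range(3)
    ]
    return mask[np.ix_(*idx)]


def _results_table(results: list) -> pd.DataFrame:
    df = pd.DataFrame([r.to_row() for r in results])
    if not df.empty:
        finite = df["p"].notna()
        adj = np.full(len(df), np.nan)
        if finite.any():
            adj[finite.to_numpy()] = fdr_adjust(df.loc[finite, "p"].to_numpy())
        df["p_fdr"] = adj
    return df


def _marker_change(base: pd.DataFrame, table: pd.DataFrame, col: str) -> pd.Series:
    """Binary per-subject change indicator (any increase over MRI visits)."""
    mri = table.dropna(subset=[col])
    first = mri.sort_values("visit_year").groupby("subject_id")[col].first()
    last = mri.sort_values("visit_year").groupby("subject_id")[col].last()
    return (last - first > 0).astype(int)


def run_analysis(
    table: pd.DataFrame,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """The full statistical battery over a long-format cohort table.

    Produces the baseline-association, progression, cognition and
    dementia results tables (raw and FDR-adjusted p per table), the
    marker-change mixed models with BLUP slope extraction, cutpoint
    survival stratification and variable-importance rankings, plus a
    JSON-serializable manifest of every model spec run.
    """
    if config is None:
        config = RunConfig()
    required = {"subject_id", "visit_year", "dementia_event", "dementia_time"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")

    base = table[table["visit_year"] == 0.0].copy()
    manifest: list[dict] = []
    bundle: dict = {}

    def _run(fits, fit_fn, data):
        results = []
        for spec in fits:
            manifest.append(
                {
                    "outcome": spec.outcome,
                    "predictor": spec.predictor,
                    "covariates": spec.covariates
                    if isinstance(spec.covariates, str)
                    else list(spec.covariates),
                    "family": spec.family,
                }
            )
            out = fit_fn(data, spec)
            results.append(out[0] if isinstance(out, tuple) else out)
        return results

    predictors = [p for p in ("alps", "pvs_wb") if p in table.columns]

    # 1. baseline cross-sectional associations (marker ~ PVS predictor)
    baseline_outcomes = [
        c for c in ("wmh", "lacunes", "microbleeds", "psmd", "md_median")
        if c in base.columns
    ]
    specs = [
        ModelSpec(outcome=o, predictor=p, covariates="base", family="linear")
        for p in predictors
        for o in baseline_outcomes
    ]
    bundle["baseline"] = _results_table(_run(specs, fit_linear, base))

    # 2. progression: baseline predictor x time on continuous markers,
    #    logistic on binary marker change
    prog_results = []
    for p in predictors:
        pred_base = base.set_index("subject_id")[p]
        longit = table.copy()
        longit[f"{p}0"] = longit["subject_id"].map(pred_base)
        for o in ("wmh", "md_median", "psmd"):
            if o not in table.columns:
                continue
            spec = ModelSpec(
                outcome=o, predictor=f"{p}0", covariates="base", family="lmm"
            )
            manifest.append({**spec.__dict__, "covariates": "base"})
            res, _ = fit_lmm(longit.dropna(subset=[o]), spec)
            prog_results.append(res)
        for o in ("lacunes", "microbleeds"):
            if o not in table.columns:
                continue
            change = _marker_change(base, table, o)
            logit_df = base.copy()
            logit_df[f"{o}_change"] = logit_df["subject_id"].map(change)
            spec = ModelSpec(
                outcome=f"{o}_change", predictor=p, covariates="base",
                family="logistic",
            )
            manifest.append({**spec.__dict__, "covariates": "base"})
            try:
                prog_results.append(fit_logistic(logit_df, spec))
            except ValueError:
                pass  # e.g. no changes at all: recorded by absence
    bundle["progression"] = _results_table(prog_results)

    # 3. cognition: baseline predictor x time on each domain
    cog_results = []
    for p in predictors:
        pred_base = base.set_index("subject_id")[p]
        for d in ("cog_global", "cog_exec", "cog_memory", "cog_speed"):
            if d not in table.columns:
                continue
            longit = table.dropna(subset=[d]).copy()
            longit[f"{p}0"] = longit["subject_id"].map(pred_base)
            spec = ModelSpec(
                outcome=d, predictor=f"{p}0", covariates="base_nart", family="lmm"
            )
            manifest.append({**spec.__dict__, "covariates": "base_nart"})
            res, _ = fit_lmm(longit, spec)
            cog_results.append(res)
    bundle["cognition"] = _results_table(cog_results)

    # 4. dementia: Cox with nested covariate sets
    n_events = int(base["dementia_event"].sum())
    if n_events == 0:
        bundle["dementia"] = {"skipped": True, "reason": "zero events"}
        bundle["cutpoint"] = {"skipped": True, "reason": "zero events"}
    else:
        cox_results = []
        for p in predictors:
            for covset in ("base_nart", "base_nart_csvd", "base_nart_md",
                           "base_nart_psmd"):
                spec = ModelSpec(
                    outcome="dementia_event", predictor=p, covariates=covset,
                    family="cox",
                )
                manifest.append({**spec.__dict__, "covariates": covset})
                try:
                    cox_results.append(fit_cox(base, spec))
                except ValueError as exc:
                    warnings.warn(f"cox {p}/{covset}: {exc}", stacklevel=2)
        bundle["dementia"] = _results_table(cox_results)

        # cutpoint stratification + survival curves on baseline ALPS
        if "alps" in base.columns:
            cut = best_cutpoint(
                base["alps"].to_numpy(), base["dementia_event"].to_numpy()
            )
            flagged = (
                base["alps"] <= cut.cutpoint
                if cut.direction == "<="
                else base["alps"] >= cut.cutpoint
            )
            groups = np.where(flagged, "low_alps", "high_alps")
            km = km_logrank(
                base["dementia_time"].to_numpy(),
                base["dementia_event"].to_numpy(),
                groups,
            )
            bundle["cutpoint"] = {
                "cutpoint": cut.cutpoint,
                "direction": cut.direction,
                "youden": cut.youden,
                "logrank_statistic": km["statistic"],
                "logrank_p": km["p"],
                "curves": km["curves"],
            }

    # 5. marker-change models: time slope of each PVS marker + BLUPs,
    #    then change-predicts-dementia Cox
    change_results = []
    slopes_by_marker: dict[str, pd.DataFrame] = {}
    for p in predictors:
        spec = ModelSpec(
            outcome=p, predictor=None, covariates=(), family="lmm",
            standardize=False,
        )
        manifest.append({**spec.__dict__, "covariates": []})
        res, slopes = fit_lmm(table.dropna(subset=[p]), spec)
        change_results.append(res)
        slopes_by_marker[p] = slopes.table
        if n_events >= 5:
            cox_df = base.copy()
            slope_map = slopes.table.set_index("subject_id")["slope"]
            cox_df[f"{p}_slope"] = cox_df["subject_id"].map(slope_map)
            spec = ModelSpec(
                outcome="dementia_event", predictor=f"{p}_slope",
                covariates="base_nart", family="cox",
            )
            manifest.append({**spec.__dict__, "covariates": "base_nart"})
            try:
                change_results.append(fit_cox(cox_df, spec))
            except ValueError as exc:
                warnings.warn(f"cox change {p}: {exc}", stacklevel=2)
    bundle["marker_change"] = _results_table(change_results)
    bundle["subject_slopes"] = slopes_by_marker

    # 6. variable importance for cognition change and dementia
    importance: dict[str, pd.DataFrame] = {}
    imp_base = base.set_index("subject_id")
    final_year = table["visit_year"].max()
    for d in ("cog_global", "cog_exec", "cog_memory", "cog_speed"):
        if d not in table.columns:
            continue
        t0 = table[table["visit_year"] == 0.0].set_index("subject_id")[d]
        t5 = table[table["visit_year"] == final_year].set_index("subject_id")[d]
        imp_df = imp_base.copy()
        imp_df[f"{d}_change"] = t5 - t0
        try:
            importance[d] = variable_importance(
                imp_df, f"{d}_change", seed=config.seed
            )
        except ValueError:
            continue
    try:
        importance["dementia"] = variable_importance(
            imp_base, "dementia_event", seed=config.seed
        )
    except ValueError:
        pass
    bundle["importance"] = importance
    bundle["manifest"] = manifest

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("baseline", "progression", "cognition", "dementia",
                 "marker_change"):
        obj = bundle.get(name)
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out_dir / f"{name}.csv", index=False)
        elif isinstance(obj, dict):
            (out_dir / f"{name}.json").write_text(json.dumps(obj, indent=2))
    cut = bundle.get("cutpoint")
    if isinstance(cut, dict) and "curves" in cut:
        for lab, curve in cut["curves"].items():
            curve.to_csv(out_dir / f"survival_{lab}.csv")
        meta = {k: v for k, v in cut.items() if k != "curves"}
        (out_dir / "cutpoint.json").write_text(json.dumps(meta, indent=2))
        _plot_km(cut["curves"], out_dir / "survival.png")
    for d, df in bundle.get("importance", {}).items():
        df.to_csv(out_dir / f"importance_{d}.csv", index=False)
    (out_dir / "manifest.json").write_text(
        json.dumps(bundle["manifest"], indent=2, default=str)
    )


def _plot_km(curves: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, curve in curves.items():
        ax.step(curve.index, curve.iloc[:, 0], where="post", label=str(lab))
    ax.set_xlabel("years")
    ax.set_ylabel("dementia-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def end_to_end_demo(
    seed: int = 0,
    out_dir: str | Path = "demo_out",
    fast: bool = False,
) -> dict:
    """Generate phantoms and a cohort, run both stages, render a report.

    Returns a summary dict; writes ``report.md`` plus the analysis
    bundle under ``out_dir``.  ``fast`` shrinks the cohort for smoke
    runs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = RunConfig(seed=seed, fast=fast)

    # imaging stage on closed-form phantoms
    planted = [
        ("isotropic", (1.0e-3, 1.0e-3, 1.0e-3, 1.0e-3)),
        ("anisotropic", (1.5e-3, 1.5e-3, 0.5e-3, 0.5e-3)),
        ("intermediate", (1.2e-3, 0.8e-3, 0.5e-3, 0.5e-3)),
    ]
    tissue = generate_tissue_phantom(seed=seed)
    visits = []
    expectations = {}
    for name, vals in planted:
        ph = generate_alps_phantom(*vals, seed=seed)
        expectations[name] = ph.expected["mean"]
        visits.append(
            SubjectVisit(
                subject_id=name, acquisition=ph.acquisition, tissue=tissue.maps
            )
        )
    imaging, failures = run_imaging(visits, config)
    imaging.to_csv(out_dir / "imaging_markers.csv", index=False)

    # cohort stage
    n = 60 if fast else 120
    cohort_spec = CohortSpec(n=n, seed=seed)
    table, truth = generate_cohort(cohort_spec)
    table.to_csv(out_dir / "cohort.csv", index=False)
    bundle = run_analysis(table, config, out_dir=out_dir / "analysis")

    report = _render_report(imaging, expectations, failures, bundle, truth, seed)
    (out_dir / "report.md").write_text(report)
    return {
        "imaging": imaging,
        "expectations": expectations,
        "bundle": bundle,
        "truth": truth,
        "report_path": out_dir / "report.md",
        "n_failures": len(failures),
    }


def _render_report(
    imaging: pd.DataFrame,
    expectations: dict,
    failures: list,
    bundle: dict,
    truth: dict,
    seed: int,
) -> str:
    lines = [
        "# Synthetic end-to-end run",
        "",
        f"Seed: {seed}",
        "",
        "## Imaging phantoms (computed vs planted mean ALPS)",
        "",
        "| phantom | computed | planted |",
        "|---|---|---|",
    ]
    for _, row in imaging.iterrows():
        name = row["subject_id"]
        lines.append(
            f"| {name} | {row['alps_mean']:.6f} | {expectations[name]:.6f} |"
        )
    if failures:
        lines += ["", f"Failed subjects: {failures}"]
    lines += ["", "## Cohort analysis", ""]
    for name in ("baseline", "progression", "cognition", "dementia",
                 "marker_change"):
        obj = bundle.get(name)
        lines.append(f"### {name}")
        lines.append("")
        if isinstance(obj, pd.DataFrame) and not obj.empty:
            lines.append(obj.to_markdown(index=False, floatfmt=".4g"))
        else:
            lines.append(f"(skipped: {obj})")
        lines.append("")
    cut = bundle.get("cutpoint")
    if isinstance(cut, dict) and "cutpoint" in cut:
        lines += [
            "### survival stratification",
            "",
            f"Optimal baseline ALPS cutpoint {cut['cutpoint']:.3f} "
            f"(direction {cut['direction']}, Youden J {cut['youden']:.3f}); "
            f"log-rank statistic {cut['logrank_statistic']:.3f}, "
            f"p = {cut['logrank_p']:.3g}.",
            "",
        ]
    lines += [
        "## Generating truth",
        "",
        "```json",
        json.dumps(truth, indent=2, default=float),
        "```",
        "",
    ]
    return "\n".join(lines)
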