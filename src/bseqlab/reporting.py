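"""Hourly summaries, cross-project pooling, and the end-to-end driver.

``run_analysis`` is the non-interactive equivalent of a point-and-click
session: it validates and ingests a project, pools categories, builds
window features, runs the explorative (RF + ICA) and confirmatory (PCA)
branches and optionally the SVM/permutation machinery, and writes a
markdown report with CSV artifacts.  Reports go into a versioned folder
``bseqlab_<version>/`` under the project directory; derived data (the
synchronized minute summaries and the feature matrix, reusable across
runs) go into the unversioned ``bseqlab/`` folder.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .categories import DISTANCE_LABEL, CategoryScheme, derive_base38, get_scheme, pool
from .errors import EmptyInputError, MetadataParseError, StageError
from .features import (
    FeatureMatrix,
    apply_exclusions,
    available_windows,
    build_features,
    define_windows,
)
from .ingest import load_minutes
from .metadata import ProjectBundle, load_project, validate_project
from .ml import pairwise_groups, permutation_pvalue
from .stats import ica_embed, pca_group_test, rf_select

__all__ = [
    "hourly_summary",
    "hourly_plots",
    "pool_projects",
    "run_analysis",
    "AnalysisOptions",
]

DAYS_PER_MONTH = 30.44


def hourly_summary(tables: list[pd.DataFrame],
                   scheme: CategoryScheme) -> pd.DataFrame:
    """Group mean and SD of percent time per category per hour.

    Minutes are aggregated into hour bins aligned to lights-off (hour 0
    starts at the lights-off instant; negative hours precede it).  Percent
    is category seconds over covered seconds in the bin, computed per
    animal, then averaged within group.
    """
    if not tables:
        raise EmptyInputError("no minute tables supplied")
    per_animal = []
    for table in tables:
        pooled = pool(derive_base38(table), scheme)
        cats = list(scheme.behavior_labels())
        hour = np.floor(pooled["bintodark"].to_numpy(dtype=float) / 60.0).astype(int)
        grouped = pooled.groupby(hour)
        seconds = grouped[cats].sum()
        covered = grouped["minute_index"].count() * 60.0
        pct = seconds.div(covered, axis=0) * 100.0
        pct.index.name = "hour"
        pct = pct.reset_index().melt(id_vars="hour", var_name="category",
                                     value_name="percent")
        pct["animal_id"] = str(table["animal_id"].iloc[0])
        pct["group"] = str(table["group"].iloc[0])
        per_animal.append(pct)
    stacked = pd.concat(per_animal, ignore_index=True)
    out = (stacked.groupby(["group", "category", "hour"])["percent"]
           .agg(mean="mean", sd="std", n="count").reset_index())
    out["sd"] = out["sd"].fillna(0.0)
    return out


def hourly_plots(summary: pd.DataFrame, out_pdf: str | Path) -> Path:
    """One mean+/-SD plot per category, all pages in a single PDF."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    out_pdf = Path(out_pdf)
    with PdfPages(out_pdf) as pdf:
        for category, sub in summary.groupby("category"):
            fig, ax = plt.subplots(figsize=(7, 4))
            for group, gsub in sub.groupby("group"):
                gsub = gsub.sort_values("hour")
                ax.errorbar(gsub["hour"], gsub["mean"], yerr=gsub["sd"],
                            label=str(group), capsize=2, marker="o", ms=3)
            ax.set_xlabel("hours from lights-off")
            ax.set_ylabel("% time")
            ax.set_title(category)
            ax.axvline(0, color="gray", lw=0.8, ls="--")
            ax.legend()
            fig.tight_layout()
            pdf.savefig(fig)
            plt.close(fig)
    return out_pdf


def _ingest_project(bundle: ProjectBundle) -> list[pd.DataFrame]:
    return [load_minutes(bundle, row) for row in bundle.active_experiments()]


def _age_months(row) -> float | None:
    if row.birth_date is None:
        return None
    days = (row.recording_start.date() - row.birth_date).days
    return days / DAYS_PER_MONTH


def pool_projects(master_files: list[tuple[str | Path, str]],
                  window_ids: tuple[str, ...] | None = None,
                  scheme_name: str = "berlin",
                  drop_distance: bool = True,
                  ) -> tuple[FeatureMatrix, pd.DataFrame, list[dict]]:
    """Build features for several projects and run one pooled PCA.

    Every project must provide all selected windows and the birth dates
    needed for the age covariate; a project missing either is rejected
    with the reason recorded (third return value).  Returns the pooled
    matrix and a per-animal table (project, age, group, PC1).
    """
    scheme = get_scheme(scheme_name)
    matrices, annotations, rejected = [], [], []
    for master_file, project_id in master_files:
        try:
            bundle = load_project(master_file, project_id)
            rows = bundle.active_experiments()
            if any(r.birth_date is None for r in rows):
                raise MetadataParseError("birth_date missing for some animals")
            tables = _ingest_project(bundle)
            span = _common_span(tables)
            windows = define_windows(bundle.lab, span)
            if window_ids:
                windows = [w for w in windows if w.id in window_ids]
            avail = available_windows(tables, windows)
            missing = {w.id for w in windows} - {w.id for w in avail}
            if missing:
                raise EmptyInputError(
                    f"window(s) {sorted(missing)} lack data for some animals"
                )
            matrix = apply_exclusions(
                build_features(tables, windows, scheme,
                               drop_distance=drop_distance),
                bundle.experiments,
            )
            ages = {(r.animal_id, r.test_id): _age_months(r) for r in rows}
        except Exception as exc:  # record the reason, keep pooling
            rejected.append({"project": str(project_id), "reason": str(exc)})
            continue
        matrices.append(matrix)
        annotations.extend(
            {"project": str(project_id), "animal_id": a, "test_id": t,
             "age_months": ages[(a, t)]}
            for a, t in zip(matrix.animal_ids, matrix.test_ids)
        )
    if not matrices:
        raise EmptyInputError("no project could be pooled")
    pooled = FeatureMatrix(
        data=pd.concat([m.data for m in matrices], axis=0, ignore_index=True),
        groups=pd.concat([m.groups for m in matrices], ignore_index=True),
        animal_ids=pd.concat([m.animal_ids for m in matrices], ignore_index=True),
        test_ids=pd.concat([m.test_ids for m in matrices], ignore_index=True),
        scheme_name=scheme.name,
        window_ids=matrices[0].window_ids,
    )
    from sklearn.decomposition import PCA

    X = pooled.data.to_numpy(dtype=float)
    pc1 = PCA(n_components=1).fit_transform(X)[:, 0]
    table = pd.DataFrame(annotations)
    table["group"] = pooled.groups.to_numpy()
    table["PC1"] = pc1
    return pooled, table, rejected


def _common_span(tables: list[pd.DataFrame]) -> tuple[float, float]:
    starts = [float(t["bintodark"].min()) for t in tables]
    ends = [float(t["bintodark"].max()) + 1.0 for t in tables]
    return min(starts), max(ends)


@dataclass
class AnalysisOptions:
    scheme: str = "berlin"
    windows: tuple[str, ...] = ()   # empty = all available
    drop_distance: bool = False
    do_ml: bool = False
    kernel: str = "radial"
    n_perm: int = 100
    repeats: int = 100
    seed: int = 0
    make_plots: bool = True


@dataclass
class AnalysisResult:
    report_path: Path
    matrix: FeatureMatrix
    group_test: object
    selection: object
    ica: pd.DataFrame
    ml_results: list = field(default_factory=list)
    report_dir: Path | None = None


def run_analysis(master_file: str | Path, project_id: str,
                 options: AnalysisOptions | None = None) -> AnalysisResult:
    """Run the whole pipeline on one project and write the report bundle.

    Stages: validate -> ingest -> synchronize -> pool categories -> window
    features -> RF/ICA + PCA test (-> SVM permutation inference) -> report.
    Errors carry the name of the stage that raised them.  Input data files
    are never modified.
    """
    opts = options or AnalysisOptions()

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    bundle = stage("metadata", load_project, master_file, project_id)
    issues = validate_project(bundle)
    hard = [i for i in issues if i.severity == "error"]
    if hard:
        raise StageError("metadata", MetadataParseError(
            "; ".join(f"{i.field}: {i.message}" for i in hard)))

    tables = stage("ingest", _ingest_project, bundle)
    scheme = get_scheme(opts.scheme)
    span = _common_span(tables)
    windows = stage("features", define_windows, bundle.lab, span)
    avail = stage("features", available_windows, tables, windows)
    if opts.windows:
        avail = [w for w in avail if w.id in opts.windows]
    matrix = stage("features", build_features, tables, avail, scheme,
                   opts.drop_distance)
    matrix = stage("features", apply_exclusions, matrix, bundle.experiments)

    selection = stage("multivariate", rf_select, matrix, opts.seed)
    ica = stage("multivariate", ica_embed, matrix, selection.selected,
                opts.seed)
    group_test = stage("multivariate", pca_group_test, matrix)

    ml_results = []
    if opts.do_ml:
        for i, sub in enumerate(stage("ml", pairwise_groups, matrix)):
            ml_results.append(stage(
                "ml", permutation_pvalue, sub,
                kernel=opts.kernel, n_perm=opts.n_perm,
                seed=opts.seed + i, repeats=opts.repeats,
            ))

    # -- write artifacts ---------------------------------------------------
    report_dir = bundle.project_dir / f"bseqlab_{__version__}"
    derived_dir = bundle.project_dir / "bseqlab"
    report_dir.mkdir(parents=True, exist_ok=True)
    derived_dir.mkdir(parents=True, exist_ok=True)

    for table in tables:
        a, t = str(table["animal_id"].iloc[0]), str(table["test_id"].iloc[0])
        table.to_csv(derived_dir / f"sync_minutes_{a}_{t}.csv", index=False)
    matrix.to_frame().to_csv(derived_dir / "feature_matrix.csv", index=False)
    ica.drop(columns="group").join(matrix.groups).to_csv(
        report_dir / "ica_coordinates.csv", index=True
    )
    if ml_results:
        pd.DataFrame({
            f"pair_{i + 1}": pd.Series(r.permutation_accuracies)
            for i, r in enumerate(ml_results)
        }).to_csv(report_dir / "permutation_accuracies.csv", index=False)

    summary = hourly_summary(tables, scheme)
    summary.to_csv(report_dir / "hourly_summary.csv", index=False)
    if opts.make_plots:
        hourly_plots(summary, report_dir / "hourly_plots.pdf")
        _ica_plot(ica, report_dir / "ica_3d.png")
        for i, res in enumerate(ml_results):
            _perm_plot(res, report_dir / f"permutation_cloud_{i + 1}.png")

    report_path = report_dir / "report.md"
    report_path.write_text(_render_report(
        bundle, opts, matrix, selection, group_test, ml_results, issues
    ))
    return AnalysisResult(report_path=report_path, matrix=matrix,
                          group_test=group_test, selection=selection,
                          ica=ica, ml_results=ml_results,
                          report_dir=report_dir)


def _ica_plot(ica: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = [c for c in ica.columns if c.startswith("IC")]
    fig = plt.figure(figsize=(6, 5))
    if len(comps) >= 3:
        ax = fig.add_subplot(111, projection="3d")
        for group, sub in ica.groupby("group"):
            ax.scatter(sub["IC1"], sub["IC2"], sub["IC3"], label=str(group))
        ax.set_xlabel("IC1"); ax.set_ylabel("IC2"); ax.set_zlabel("IC3")
    else:
        ax = fig.add_subplot(111)
        for group, sub in ica.groupby("group"):
            ax.scatter(sub[comps[0]],
                       sub[comps[1]] if len(comps) > 1 else 0 * sub[comps[0]],
                       label=str(group))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _perm_plot(result, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(result.permutation_accuracies, bins=20, color="steelblue")
    ax.axvline(result.accuracy, color="red", lw=2,
               label=f"observed = {result.accuracy:.3f}")
    ax.set_xlabel("pooled accuracy")
    ax.set_ylabel("permutations")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _render_report(bundle, opts, matrix, selection, group_test,
                   ml_results, issues) -> str:
    lines = [
        f"# bseqlab analysis report — {bundle.master.proj_name}",
        "",
        f"- software: bseqlab {__version__}",
        f"- generated: (deterministic content; seed {opts.seed})",
        f"- scheme: {matrix.scheme_name}; windows: {', '.join(matrix.window_ids)}",
        f"- animals analyzed: {matrix.n_rows} ("
        + ", ".join(f"{g}: {int(n)}"
                    for g, n in matrix.groups.value_counts().items())
        + ")",
        f"- feature columns: {matrix.data.shape[1]}",
        "",
        "## Metadata validation",
        "",
    ]
    if issues:
        lines += [f"- {i.severity}: {i.field}: {i.message}" for i in issues]
    else:
        lines.append("- no issues")
    lines += [
        "",
        "## Variable selection (double random forest)",
        "",
        f"- seed: {selection.seed}",
        f"- selected {selection.n_selected} variable(s):",
        "",
    ]
    lines += [f"  - {name} (importance {selection.second_pass[name]:.4f})"
              for name in selection.selected]
    r_text = ("" if group_test.effect_size_r is None
              else f"; effect size r = |Z|/sqrt(n) = {group_test.effect_size_r:.3f}")
    lines += [
        "",
        "## PCA group test (confirmatory)",
        "",
        f"- test: {group_test.test_name}",
        f"- statistic = {group_test.statistic:.4f}, "
        f"p = {group_test.p_value:.5g}{r_text}",
        f"- PC1 explains "
        f"{group_test.explained_variance_ratio[0] * 100:.1f}% of variance",
    ]
    if ml_results:
        lines += ["", "## SVM validation with permutation null", ""]
        for res in ml_results:
            lines += [
                f"- kernel {res.kernel}, scheme {res.scheme}, "
                f"seed {res.seed}, repeats {res.repeats}",
                f"  accuracy = {res.accuracy:.3f}, kappa = {res.kappa:.3f}",
                f"  permutations: {res.n_permutations}; "
                f"exceedance k = {res.n_exceeding}; "
                f"p = {res.p_value:.4f}; "
                f"p-range (95% binomial CI) = "
                f"[{res.p_range[0]:.4f}, {res.p_range[1]:.4f}]",
            ]
    lines.append("")
    return "\n".join(lines)
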