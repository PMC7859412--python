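"""Summary surfaces and the end-to-end pipeline.

Produces the paper-style reporting artefacts for a finished analysis: the
main-cluster x disease-category contingency table, the cluster x
actuarial-band table (with the negative-slope column kept separate), and the
per-cluster summary of member diseases' median onset ages. ``run_pipeline``
chains everything: counts -> rates -> standardised curves -> clustering with
model selection -> actuarial banding -> summaries, writing every
intermediate artefact plus a machine-readable manifest.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .actuarial import BANDS, DEFAULT_MIN_POSITIVE_AGES, classify_all
from .clustering import ALGORITHMS, LINKAGES, OnsetCurveClusterer, split_main_outlier
from .exceptions import MissingMetadataError, StandardisationError
from .rates import median_onset_table, rates_table, standardised_table

#: the default disease-category vocabulary (ICD-10-chapter-like, 15 labels)
DEFAULT_CATEGORIES = (
    "cardiovascular",
    "cancers",
    "respiratory",
    "eye",
    "musculoskeletal",
    "endocrine",
    "haematological/immunological",
    "infections",
    "ear",
    "neurological",
    "genitourinary",
    "digestive",
    "benign neoplasms",
    "skin",
    "psychiatric",
)

#: column order for cluster x band tables: positive-slope bands by decreasing
#: adjusted R², then the negative-beta column, then unclassifiable curves
BAND_COLUMNS = list(BANDS) + ["unclassified"]


def crosstab_cluster_category(partition: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Main-cluster x disease-category counts with row/column totals.

    ``partition`` is the output of :func:`split_main_outlier`; only
    main-cluster diseases enter the table. ``meta`` must have a ``category``
    column indexed (or indexable) by disease_id. Unknown categories are kept
    (the method generalises beyond any fixed disease panel).
    """
    meta = meta.set_index("disease_id") if "disease_id" in meta.columns else meta
    main = partition[partition["is_main"]]
    missing = main.index.difference(meta.index)
    if len(missing):
        raise MissingMetadataError(f"no metadata for diseases: {missing.tolist()}")
    cats = meta.loc[main.index, "category"]
    tab = pd.crosstab(main["main_label"].astype(int), cats, margins=True, margins_name="Total")
    tab.index.name = "cluster"
    return tab


def crosstab_cluster_band(partition: pd.DataFrame, verdicts: pd.DataFrame) -> pd.DataFrame:
    """Cluster x actuarial-band counts, main clusters then outlier clusters.

    Rows are ``"Cluster i"`` for main clusters and ``"Outlier j"`` for
    outlier clusters; columns follow BAND_COLUMNS (the negative-beta column
    kept separate from the adjusted-R² bands). A total row is appended.
    """
    missing = partition.index.difference(verdicts.index)
    if len(missing):
        raise MissingMetadataError(f"no verdicts for diseases: {missing.tolist()}")
    df = partition.join(verdicts["band"])
    df["row"] = np.where(
        df["is_main"],
        "Cluster " + df["main_label"].astype(str),
        "Outlier " + df["outlier_label"].astype(str),
    )
    tab = pd.crosstab(df["row"], df["band"]).reindex(columns=BAND_COLUMNS, fill_value=0)
    row_order = [f"Cluster {i}" for i in sorted(df.loc[df.is_main, "main_label"].unique())] + [
        f"Outlier {i}" for i in sorted(df.loc[~df.is_main, "outlier_label"].unique())
    ]
    tab = tab.reindex(row_order, fill_value=0)
    tab.loc["Total"] = tab.sum(axis=0)
    tab.index.name = "cluster"
    return tab


def cluster_median_summary(partition: pd.DataFrame, medians: pd.DataFrame) -> pd.DataFrame:
    """Per-main-cluster median and IQR of member diseases' median onset ages.

    ``medians`` is the per-disease table from :func:`median_onset_table`.
    Rows are ordered by main label (cluster 1 = oldest onset by
    construction).
    """
    main = partition[partition["is_main"]]
    joined = main.join(medians["median"])
    rows = []
    for label, grp in joined.groupby(joined["main_label"].astype(int)):
        vals = grp["median"].to_numpy()
        rows.append(
            {
                "main_label": label,
                "n_diseases": len(vals),
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
            }
        )
    return pd.DataFrame(rows).set_index("main_label").sort_index()


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs for the end-to-end run (clustering budget and fit thresholds)."""

    algorithms: tuple = ALGORITHMS
    linkages: tuple = LINKAGES
    k_max: int = 30
    n_refs: int = 50
    gap_reference: str = "pca"
    min_positive_ages: int = DEFAULT_MIN_POSITIVE_AGES
    trim_ages: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("algorithms", "linkages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def run_pipeline(
    counts: pd.DataFrame,
    meta: pd.DataFrame | None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Rates -> clustering (full model selection) -> banding -> summaries.

    Diseases whose curves cannot be standardised (all-zero) are excluded
    from clustering and flagged; per-disease fit failures are kept in the
    verdicts table as ``unclassified``. Returns a dict of DataFrames (and
    the fitted clusterer); when ``out_dir`` is given, every artefact is also
    written as CSV plus a ``manifest.json`` and plain-text ``summary.txt``.

    The run is a pure function of (counts, meta, config, seed): rerunning
    with identical inputs reproduces every output byte for byte.
    """
    config = config or PipelineConfig()

    rates = rates_table(counts, trim=config.trim_ages)
    totals = rates.sum(axis=1)
    flagged = totals[totals <= 0].index.tolist()
    clusterable = rates.drop(index=flagged)
    if clusterable.shape[0] < 3:
        raise StandardisationError("fewer than 3 diseases with nonzero curves")
    std = standardised_table(clusterable)
    medians = median_onset_table(counts[counts["disease_id"].isin(clusterable.index)],
                                 trim=config.trim_ages)

    clusterer = OnsetCurveClusterer(
        algorithms=config.algorithms,
        linkages=config.linkages,
        k_max=config.k_max,
        n_refs=config.n_refs,
        gap_reference=config.gap_reference,
        random_state=seed,
    ).fit(std.to_numpy())
    partition = split_main_outlier(clusterer.labels_, std.index, medians["median"])

    fits, verdicts = classify_all(clusterable, min_positive=config.min_positive_ages)

    band_tab = crosstab_cluster_band(partition, verdicts)
    med_tab = cluster_median_summary(partition, medians)
    cat_tab = None
    if meta is not None:
        cat_tab = crosstab_cluster_category(partition, meta)

    diagnostics = {
        "selected_algorithm": clusterer.algorithm_,
        "selected_linkage": clusterer.linkage_,
        "n_clusters": clusterer.n_clusters_,
        "cophenetic_scores": clusterer.cophenetic_scores_,
        "dunn_scores": {a: float(v) for a, v in clusterer.dunn_scores_.items()},
        "gap": {
            a: {
                "ks": r.ks.tolist(),
                "gap": r.gap.tolist(),
                "s": r.s.tolist(),
                "chosen_k": r.chosen_k,
            }
            for a, r in clusterer.gap_results_.items()
        },
        "flagged_all_zero": flagged,
    }

    result = {
        "rates": rates,
        "standardised": std,
        "medians": medians,
        "partition": partition,
        "fits": fits,
        "verdicts": verdicts,
        "crosstab_band": band_tab,
        "crosstab_category": cat_tab,
        "cluster_medians": med_tab,
        "diagnostics": diagnostics,
        "clusterer": clusterer,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rates.to_csv(out / "rates.csv")
        std.to_csv(out / "std.csv")
        medians.to_csv(out / "medians.csv")
        assignments = partition.copy()
        assignments.insert(0, "algorithm", clusterer.algorithm_)
        assignments.insert(1, "k", clusterer.n_clusters_)
        assignments.to_csv(out / "assignments.csv")
        fits.to_csv(out / "fits.csv")
        verdicts.to_csv(out / "verdicts.csv")
        band_tab.to_csv(out / "crosstab_band.csv")
        if cat_tab is not None:
            cat_tab.to_csv(out / "crosstab_category.csv")
        med_tab.to_csv(out / "cluster_medians.csv")
        (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2, sort_keys=True))
        manifest = {
            "seed": seed,
            "config": asdict(config),
            "n_diseases": int(rates.shape[0]),
            "n_clustered": int(std.shape[0]),
            "ardkit_version": __version__,
            "python_version": platform.python_version(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (out / "summary.txt").write_text(_text_summary(result))

    return result


def _text_summary(result: dict) -> str:
    diag = result["diagnostics"]
    part = result["partition"]
    lines = [
        "ardkit pipeline summary",
        "=======================",
        f"diseases analysed:       {result['rates'].shape[0]}",
        f"diseases clustered:      {result['standardised'].shape[0]}",
        f"all-zero curves flagged: {len(diag['flagged_all_zero'])}",
        f"selected algorithm:      {diag['selected_algorithm']} "
        f"(linkage={diag['selected_linkage']}, k={diag['n_clusters']})",
        f"main clusters:           {int(part['is_main'].sum())} diseases in "
        f"{part.loc[part.is_main, 'main_label'].nunique()} clusters",
        f"outlier clusters:        {int((~part['is_main']).sum())} diseases in "
        f"{part.loc[~part.is_main, 'outlier_label'].nunique()} clusters",
        "",
        "band counts:",
    ]
    for band, count in result["verdicts"]["band"].value_counts().items():
        lines.append(f"  {band:24s} {count}")
    lines.append("")
    lines.append("cluster median onset ages:")
    for label, row in result["cluster_medians"].iterrows():
        lines.append(
            f"  cluster {label}: median {row['median']:.1f}y "
            f"(IQR {row['q25']:.1f}-{row['q75']:.1f}), n={int(row['n_diseases'])}"
        )
    return "\n".join(lines) + "\n"
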