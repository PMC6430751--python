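"""Controlled evaluation of imputation strategies: delete, fill, model, compare.

The mini-study takes a fully observed harvest table, deletes a known
fraction of cells completely at random, refills the holes with each
registered imputer, and trains the same grid of symbolic-regression
settings on every variant and on the untouched table with identical
splits and seeds.  Because the complete data are in hand, the study can
measure what the proprietary-data workflow could only argue for: how much
each imputation method inflates training/testing error and the
overfitting gap relative to the complete-data baseline.

PCA diagnostics operationalise the "no evident clustering" check: all
variants are projected onto principal axes fitted to the pooled
standardised data, and the displacement between dataset centroids in the
PC1-PC2 plane is reported in units of the pooled score SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datasets import PRODUCT_COL, CultureTable
from .generate import inject_gaps
from .impute import mean_substitute, random_substitute
from .sr import SRConfig, run_sr, sample_grid_configs, split_train_test

IMPUTERS = {"mean": mean_substitute, "random": random_substitute}

#: reduced hyper-parameter grid used for repeated directional studies
SMALL_GRID_DOMAIN = {
    "population_size": (5, 50),
    "n_generations": (5, 50),
    "max_genes": (1, 2, 3),
    "max_depth": (1, 2),
}


@dataclass
class MiniStudyResult:
    """Per-(imputer x SR setting) error table from one deletion experiment."""

    gap_fraction: float
    runs: pd.DataFrame  # dataset, setting, TRE, TEE, overfit, overfit_delta
    seeds: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Grid-average errors and |overfit delta| per dataset variant."""
        g = self.runs.assign(abs_delta=self.runs["overfit_delta"].abs()).groupby("dataset")
        return g[["TRE", "TEE", "overfit", "abs_delta"]].mean()

    def error_similarity(self) -> pd.Series:
        """Grid-average |TRE - TRE_complete| + |TEE - TEE_complete| per variant.

        The headline comparison: how close each imputed variant's error
        magnitudes stay to the complete-data baseline, averaged over the
        SR settings grid.  Smaller is better.
        """
        r = self.runs.pivot(index="setting", columns="dataset", values=["TRE", "TEE"])
        out = {}
        for v in r["TRE"].columns:
            if v == "complete":
                continue
            out[v] = float(
                (r["TEE"][v] - r["TEE"]["complete"]).abs().mean()
                + (r["TRE"][v] - r["TRE"]["complete"]).abs().mean()
            )
        return pd.Series(out, name="error_similarity")

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [f"Deletion mini-study at {self.gap_fraction:.1%} MCAR gaps"]
        for name, row in agg.iterrows():
            lines.append(
                f"  {name:>8}: mean TRE={row.TRE:.4g}  TEE={row.TEE:.4g}  "
                f"overfit={row.overfit:.4g}  |delta vs complete|={row.abs_delta:.4g}"
            )
        return "\n".join(lines)


@dataclass
class PcaDiagnostics:
    """Shared-axis PCA of several dataset variants."""

    variance_explained: np.ndarray
    projections: dict  # name -> (n, k) score array
    centroid_displacement: float

    @property
    def top2_variance(self) -> float:
        return float(self.variance_explained[:2].sum())


def _features(table: CultureTable):
    X = table.data[table.param_columns]
    y = table.data[PRODUCT_COL]
    return X, y


def deletion_experiment(
    complete: CultureTable,
    gap_fraction: float,
    imputers=("mean", "random"),
    sr_configs=None,
    n_settings: int = 38,
    grid_domain: dict = None,
    train_fraction: float = 0.67,
    seed: int = 0,
) -> MiniStudyResult:
    """Delete, impute with every method, model every variant identically.

    One MCAR mask at ``gap_fraction`` is shared by all imputers; every SR
    setting is run on the complete table and on each imputed variant with
    the same split and the same run seed, so differences in TRE/TEE/overfit
    are attributable to the imputation alone.
    """
    unknown = [name for name in imputers if name not in IMPUTERS]
    if unknown:
        raise ValueError(f"unknown imputers: {unknown}")
    if complete.mask.to_numpy().any():
        raise ValueError("deletion experiment requires a fully observed table")

    rng = np.random.default_rng(seed)
    mask_seed, split_seed, random_fill_seed, grid_seed = (
        int(s) for s in rng.integers(0, 2**31 - 1, size=4)
    )
    masked = inject_gaps(complete, gap_fraction, mask_seed)
    if masked.table.mask.all(axis=0).any():
        raise ValueError("gap fraction leaves at least one column fully missing")

    variants = {"complete": complete}
    for name in imputers:
        fn = IMPUTERS[name]
        if name == "random":
            variants[name] = fn(masked.table, seed=random_fill_seed).filled
        else:
            variants[name] = fn(masked.table).filled

    if sr_configs is None:
        sr_configs = sample_grid_configs(n_settings, grid_seed, grid_domain)
    run_seeds = rng.integers(0, 2**31 - 1, size=len(sr_configs))

    ids = list(complete.data.index)
    train_ids, test_ids = split_train_test(ids, train_fraction, split_seed)

    rows = []
    for i, (cfg, s) in enumerate(zip(sr_configs, run_seeds)):
        cfg_seeded = replace(cfg, seed=int(s))
        X, y = _features(complete)
        baseline = run_sr(X, y, train_ids, test_ids, cfg_seeded)
        for name, table in variants.items():
            if name == "complete":
                res = baseline
            else:
                Xv, yv = _features(table)
                res = run_sr(Xv, yv, train_ids, test_ids, cfg_seeded)
            rows.append(
                {
                    "dataset": name,
                    "setting": i,
                    "grid_point": cfg.grid_point(),
                    "TRE": res.TRE,
                    "TEE": res.TEE,
                    "overfit": res.overfit,
                    "overfit_delta": res.overfit - baseline.overfit,
                }
            )
    runs = pd.DataFrame(rows)
    seeds = {
        "seed": seed,
        "mask_seed": mask_seed,
        "split_seed": split_seed,
        "random_fill_seed": random_fill_seed,
        "run_seeds": [int(s) for s in run_seeds],
    }
    return MiniStudyResult(masked.gap_fraction, runs, seeds)


def pca_bias_check(datasets: dict, n_components: int = None) -> PcaDiagnostics:
    """Project dataset variants onto principal axes of the pooled data.

    Columns are centred and scaled by pooled statistics (the anonymised
    parameters have incommensurate units).  The centroid displacement is
    the largest pairwise distance between variant centroids in the
    PC1-PC2 plane, in units of the pooled PC-score SD.
    """
    blocks = {}
    columns = None
    for name, ds in datasets.items():
        block = ds.params if isinstance(ds, CultureTable) else pd.DataFrame(ds)
        if columns is None:
            columns = list(block.columns)
        elif list(block.columns) != columns:
            raise ValueError("datasets must share identical columns")
        if block.isna().to_numpy().any():
            raise ValueError(f"dataset {name!r} still contains missing values")
        blocks[name] = block.to_numpy(dtype=float)

    pooled = np.vstack(list(blocks.values()))
    mu, sd = pooled.mean(axis=0), pooled.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    pooled_z = (pooled - mu) / sd
    k = n_components or min(pooled_z.shape)
    pca = PCA(n_components=k).fit(pooled_z)

    projections = {name: pca.transform((b - mu) / sd) for name, b in blocks.items()}
    pooled_scores = pca.transform(pooled_z)[:, :2]
    score_sd = float(np.sqrt(pooled_scores.var(axis=0, ddof=1).mean()))
    centroids = [p[:, :2].mean(axis=0) for p in projections.values()]
    disp = 0.0
    for i in range(len(centroids)):
        for j in range(i + 1, len(centroids)):
            disp = max(disp, float(np.linalg.norm(centroids[i] - centroids[j])))
    disp = disp / score_sd if score_sd > 0 else 0.0
    return PcaDiagnostics(pca.explained_variance_ratio_, projections, disp)


def training_fraction_study(
    variants: dict,
    config: SRConfig,
    fractions=(0.67, 0.85, 0.90),
    n_seeds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean overfit per (training fraction x dataset variant).

    Each fraction/variant cell averages ``n_seeds`` runs with fresh splits
    and run seeds; the report adds each variant's overfit change relative
    to the smallest fraction, the quantity that shows whether enlarging
    the training set rescues a poorly imputed dataset.
    """
    fractions = sorted(fractions)
    rng = np.random.default_rng(seed)
    rows = []
    for s in rng.integers(0, 2**31 - 1, size=n_seeds):
        srng = np.random.default_rng(int(s))
        for frac in fractions:
            split_seed, run_seed = (int(v) for v in srng.integers(0, 2**31 - 1, size=2))
            for name, table in variants.items():
                X, y = _features(table)
                train_ids, test_ids = split_train_test(list(X.index), frac, split_seed)
                res = run_sr(X, y, train_ids, test_ids, replace(config, seed=run_seed))
                rows.append({"variant": name, "fraction": frac, "overfit": res.overfit,
                             "TRE": res.TRE, "TEE": res.TEE})
    df = pd.DataFrame(rows)
    report = df.groupby(["variant", "fraction"], as_index=False)[["TRE", "TEE", "overfit"]].mean()
    base_frac = fractions[0]
    base = report[report["fraction"] == base_frac].set_index("variant")["overfit"]
    report["overfit_vs_baseline"] = [
        row.overfit - base[row.variant] for row in report.itertuples()
    ]
    report["relative_change"] = [
        (row.overfit - base[row.variant]) / abs(base[row.variant])
        if base[row.variant] != 0 else np.nan
        for row in report.itertuples()
    ]
    return report
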