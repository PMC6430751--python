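"""Multigene evolutionary symbolic regression with least-squares gene weights.

Product titre is modelled as a linear combination of evolved expression
trees ("genes"):

    titre = w0 + w1 * g1(x) + ... + wk * gk(x),

where each gene is built from the culture parameters, ephemeral constants
and the arithmetic function set {+, -, *, protected /}.  Tree structures
evolve by tournament selection, subtree crossover and mutation with
elitism; the linear weights are re-fitted by ordinary least squares at
every evaluation (with a tiny ridge fallback for singular systems), so the
evolutionary search only has to discover useful nonlinear features.

Model quality is tracked by the root-mean-square training error (TRE) and
testing error (TEE); their gap TEE - TRE is the overfitting measure, and
|overfit_imputed - overfit_complete| quantifies how much an imputation
method perturbs downstream modelling relative to the complete data.

Conventions: a bare terminal has depth 1, so ``max_depth=1`` restricts
genes to single parameters or constants; a parameter counts as *used* by a
model when it appears in a gene whose fitted weight is non-negligible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_FUNCTIONS = ("add", "sub", "mul", "div")
_DIV_EPS = 1e-12
_WEIGHT_EPS = 1e-10

#: the canonical hyper-parameter grid for the settings study
GRID_DOMAIN = {
    "population_size": (5, 50, 500, 5000),
    "n_generations": (5, 50, 500, 5000),
    "max_genes": (1, 2, 3, 4, 10),
    "max_depth": (1, 2, 3, 4, 5, 10),
}


@dataclass(frozen=True)
class SRConfig:
    population_size: int = 500
    n_generations: int = 500
    max_genes: int = 4
    max_depth: int = 2
    function_set: tuple = DEFAULT_FUNCTIONS
    tournament_size: int = 4
    crossover_rate: float = 0.85
    mutation_rate: float = 0.1
    elitism: bool = True
    const_range: tuple = (-10.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 1 or self.n_generations < 0:
            raise ValueError("population_size >= 1 and n_generations >= 0 required")
        if self.max_genes < 1 or self.max_depth < 1:
            raise ValueError("max_genes and max_depth must be >= 1")
        if not 0 <= self.crossover_rate + self.mutation_rate <= 1:
            raise ValueError("crossover_rate + mutation_rate must lie in [0, 1]")

    def grid_point(self) -> tuple:
        return (self.population_size, self.n_generations, self.max_genes, self.max_depth)


# ---------------------------------------------------------------------------
# expression trees (immutable tuples: ("var", j) | ("const", v) | (op, l, r))

def _protected_div(a, b):
    out = np.where(np.abs(b) < _DIV_EPS, 1.0, a / np.where(np.abs(b) < _DIV_EPS, 1.0, b))
    return out


_BINARY = {"add": np.add, "sub": np.subtract, "mul": np.multiply, "div": _protected_div}


def tree_depth(node) -> int:
    if node[0] in ("var", "const"):
        return 1
    return 1 + max(tree_depth(node[1]), tree_depth(node[2]))


def tree_terminal_vars(node, out: set) -> set:
    if node[0] == "var":
        out.add(node[1])
    elif node[0] != "const":
        tree_terminal_vars(node[1], out)
        tree_terminal_vars(node[2], out)
    return out


def eval_tree(node, X: np.ndarray) -> np.ndarray:
    kind = node[0]
    if kind == "var":
        return X[:, node[1]]
    if kind == "const":
        return np.full(X.shape[0], node[1])
    with np.errstate(all="ignore"):
        return _BINARY[kind](eval_tree(node[1], X), eval_tree(node[2], X))


def tree_to_infix(node, names) -> str:
    kind = node[0]
    if kind == "var":
        return str(names[node[1]])
    if kind == "const":
        return f"{node[1]:.4g}"
    sym = {"add": "+", "sub": "-", "mul": "*", "div": "/"}[kind]
    return f"({tree_to_infix(node[1], names)} {sym} {tree_to_infix(node[2], names)})"


def _node_paths(node, prefix=()):
    yield prefix
    if node[0] not in ("var", "const"):
        yield from _node_paths(node[1], prefix + (1,))
        yield from _node_paths(node[2], prefix + (2,))


def _get_subtree(node, path):
    for step in path:
        node = node[step]
    return node


def _replace_subtree(node, path, new):
    if not path:
        return new
    step, rest = path[0], path[1:]
    children = list(node)
    children[step] = _replace_subtree(node[step], rest, new)
    return tuple(children)


def _random_terminal(rng, n_vars, const_range):
    if n_vars and rng.random() < 0.7:
        return ("var", int(rng.integers(n_vars)))
    return ("const", float(rng.uniform(*const_range)))


def _random_tree(rng, n_vars, depth_budget, config, full=False):
    """Grow (or full) initialisation respecting the depth budget."""
    if depth_budget <= 1 or (not full and rng.random() < 0.3):
        return _random_terminal(rng, n_vars, config.const_range)
    op = config.function_set[rng.integers(len(config.function_set))]
    return (
        op,
        _random_tree(rng, n_vars, depth_budget - 1, config, full),
        _random_tree(rng, n_vars, depth_budget - 1, config, full),
    )


# ---------------------------------------------------------------------------
# models and run records

@dataclass
class SRModel:
    """A multigene model: expression trees plus least-squares weights."""

    genes: tuple  # tuple of trees
    weights: np.ndarray  # (intercept, w1..wk)
    terminal_names: list

    @property
    def intercept(self) -> float:
        return float(self.weights[0])

    @property
    def used_parameters(self) -> set:
        used = set()
        for gene, w in zip(self.genes, self.weights[1:]):
            if abs(w) > _WEIGHT_EPS:
                idx = tree_terminal_vars(gene, set())
                used.update(self.terminal_names[j] for j in idx)
        return used

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.terminal_names)
        out = np.full(X.shape[0], self.intercept)
        for gene, w in zip(self.genes, self.weights[1:]):
            out = out + w * eval_tree(gene, X)
        return out

    def expression(self) -> str:
        parts = [f"{self.intercept:.4g}"]
        for gene, w in zip(self.genes, self.weights[1:]):
            parts.append(f"{w:+.4g}*{tree_to_infix(gene, self.terminal_names)}")
        return " ".join(parts)

    def summary(self) -> str:
        lines = [
            f"Multigene SR model: {len(self.genes)} gene(s), "
            f"uses {sorted(self.used_parameters)}",
            f"  prediction = {self.expression()}",
        ]
        return "\n".join(lines)


@dataclass
class SRRunResult:
    """One training run: the model, its errors and the split it saw."""

    model: SRModel
    TRE: float
    TEE: float
    config: SRConfig
    train_ids: list
    test_ids: list
    fitness_history: np.ndarray = field(repr=False, default=None)

    @property
    def overfit(self) -> float:
        return self.TEE - self.TRE


@dataclass
class RecurrenceTable:
    """How many of n_runs produced a final model using each parameter."""

    counts: dict
    n_runs: int

    def ranked(self) -> list:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _as_matrix(X, names=None):
    if isinstance(X, pd.DataFrame):
        if names is not None:
            missing = [n for n in names if n not in X.columns]
            if missing:
                raise ValueError(f"missing model terminals: {missing}")
            X = X[list(names)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _fit_weights(G: np.ndarray, y: np.ndarray):
    A = np.column_stack([np.ones(len(y)), G])
    if not np.all(np.isfinite(A)):
        return None, np.inf
    w, *_ = np.linalg.lstsq(A, y, rcond=None)
    if not np.all(np.isfinite(w)):
        w = np.linalg.solve(A.T @ A + 1e-8 * np.eye(A.shape[1]), A.T @ y)
    resid = A @ w - y
    if not np.all(np.isfinite(resid)):
        return None, np.inf
    return w, float(np.sqrt(np.mean(resid**2)))


# ---------------------------------------------------------------------------
# the evolutionary engine

class SymbolicRegression:
    """Model-style front end: construct with training data, then ``fit()``.

    ``fit`` evolves a population of multigene individuals and returns the
    :class:`SRRunResult` of the best individual of the final generation
    (TEE filled in only when test data were supplied).
    """

    def __init__(self, X_train, y_train, config: SRConfig, X_test=None, y_test=None,
                 terminal_names=None, train_ids=None, test_ids=None):
        if isinstance(X_train, pd.DataFrame) and terminal_names is None:
            terminal_names = list(X_train.columns)
        self.X = _as_matrix(X_train)
        self.y = np.asarray(y_train, dtype=float)
        if len(self.y) < 2:
            raise ValueError("need at least 2 training rows")
        self.X_test = _as_matrix(X_test) if X_test is not None else None
        self.y_test = np.asarray(y_test, dtype=float) if y_test is not None else None
        self.config = config
        self.names = list(terminal_names) if terminal_names else [
            f"x{j}" for j in range(self.X.shape[1])
        ]
        self.train_ids = list(train_ids) if train_ids is not None else list(range(len(self.y)))
        self.test_ids = list(test_ids) if test_ids is not None else []

    # -- genetic operators ---------------------------------------------------
    def _random_individual(self, rng):
        cfg = self.config
        n_genes = int(rng.integers(1, cfg.max_genes + 1))
        return tuple(
            _random_tree(rng, self.X.shape[1], cfg.max_depth, cfg) for _ in range(n_genes)
        )

    def _evaluate(self, ind, cache):
        hit = cache.get(ind)
        if hit is not None:
            return hit
        G = np.column_stack([eval_tree(g, self.X) for g in ind])
        w, tre = _fit_weights(G, self.y)
        cache[ind] = (w, tre)
        return w, tre

    def _tournament(self, rng, pop, fits):
        k = min(self.config.tournament_size, len(pop))
        idx = rng.integers(len(pop), size=k)
        return pop[min(idx, key=lambda i: fits[i])]

    def _crossover(self, rng, p1, p2):
        cfg = self.config
        if len(p1) > 1 and len(p2) >= 1 and rng.random() < 0.3:
            # high-level: swap in a whole gene from the second parent
            genes = list(p1)
            genes[rng.integers(len(genes))] = p2[rng.integers(len(p2))]
            return tuple(genes)
        gi, gj = rng.integers(len(p1)), rng.integers(len(p2))
        paths_i = list(_node_paths(p1[gi]))
        paths_j = list(_node_paths(p2[gj]))
        path = paths_i[rng.integers(len(paths_i))]
        donor = _get_subtree(p2[gj], paths_j[rng.integers(len(paths_j))])
        child_gene = _replace_subtree(p1[gi], path, donor)
        if tree_depth(child_gene) > cfg.max_depth:
            return p1  # depth limit: revert to the first parent
        genes = list(p1)
        genes[gi] = child_gene
        return tuple(genes)

    def _mutate(self, rng, ind):
        cfg = self.config
        genes = list(ind)
        r = rng.random()
        if r < 0.15 and len(genes) < cfg.max_genes:
            genes.append(_random_tree(rng, self.X.shape[1], cfg.max_depth, cfg))
            return tuple(genes)
        if r < 0.30 and len(genes) > 1:
            genes.pop(rng.integers(len(genes)))
            return tuple(genes)
        gi = rng.integers(len(genes))
        paths = list(_node_paths(genes[gi]))
        path = paths[rng.integers(len(paths))]
        budget = cfg.max_depth - len(path)
        new = _random_tree(rng, self.X.shape[1], max(budget, 1), cfg)
        mutated = _replace_subtree(genes[gi], path, new)
        if tree_depth(mutated) > cfg.max_depth:
            return ind
        genes[gi] = mutated
        return tuple(genes)

    # -- the generational loop -----------------------------------------------
    def fit(self) -> SRRunResult:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        cache: dict = {}
        pop = [self._random_individual(rng) for _ in range(cfg.population_size)]
        fits = [self._evaluate(ind, cache)[1] for ind in pop]
        history = [min(fits)]

        for _ in range(cfg.n_generations):
            order = int(np.argmin(fits))
            new_pop = [pop[order]] if cfg.elitism else []
            while len(new_pop) < cfg.population_size:
                r = rng.random()
                if r < cfg.crossover_rate:
                    child = self._crossover(
                        rng, self._tournament(rng, pop, fits), self._tournament(rng, pop, fits)
                    )
                elif r < cfg.crossover_rate + cfg.mutation_rate:
                    child = self._mutate(rng, self._tournament(rng, pop, fits))
                else:
                    child = self._tournament(rng, pop, fits)
                new_pop.append(child)
            pop = new_pop
            fits = [self._evaluate(ind, cache)[1] for ind in pop]
            history.append(min(fits))

        best_i = int(np.argmin(fits))
        w, tre = self._evaluate(pop[best_i], cache)
        if w is None:  # every individual degenerate; fall back to intercept
            pop[best_i] = (("const", 1.0),)
            w, tre = self._evaluate(pop[best_i], cache)
        model = SRModel(pop[best_i], np.asarray(w, dtype=float), self.names)
        tee = evaluate(model, self.X_test, self.y_test) if self.X_test is not None else np.nan
        return SRRunResult(
            model, tre, tee, cfg, self.train_ids, self.test_ids, np.asarray(history)
        )


def train_sr(X_train, y_train, config: SRConfig, **kwargs) -> SRModel:
    """Evolve a multigene model on training data and return it."""
    return SymbolicRegression(X_train, y_train, config, **kwargs).fit().model


def evaluate(model: SRModel, X, y) -> float:
    """Root-mean-square prediction error of a model on a dataset."""
    pred = model.predict(X)
    y = np.asarray(y, dtype=float)
    return float(np.sqrt(np.mean((pred - y) ** 2)))


# ---------------------------------------------------------------------------
# experiment-level helpers

def split_train_test(ids, train_fraction: float, seed: int):
    """Seeded disjoint exhaustive split; train size = round(fraction * n)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    ids = list(ids)
    n_train = int(round(train_fraction * len(ids)))
    if n_train == 0 or n_train == len(ids):
        raise ValueError("degenerate split: one side would be empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


def run_sr(X, y, train_ids, test_ids, config: SRConfig) -> SRRunResult:
    """Train on the given split of a DataFrame/Series pair and record errors."""
    Xtr, Xte = X.loc[train_ids], X.loc[test_ids]
    ytr, yte = y.loc[train_ids], y.loc[test_ids]
    return SymbolicRegression(
        Xtr, ytr, config, X_test=Xte, y_test=yte,
        train_ids=train_ids, test_ids=test_ids,
    ).fit()


def sample_grid_configs(
    n_settings: int, seed: int, grid_domain: dict = None, base: SRConfig = None
) -> list:
    """Draw distinct hyper-parameter combinations uniformly without replacement."""
    domain = dict(GRID_DOMAIN if grid_domain is None else grid_domain)
    points = list(itertools.product(*(domain[k] for k in sorted(domain))))
    if n_settings > len(points):
        raise ValueError(f"n_settings exceeds grid size {len(points)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(points), size=n_settings, replace=False)
    base = base or SRConfig()
    keys = sorted(domain)
    configs = []
    for i in chosen:
        configs.append(replace(base, **dict(zip(keys, points[i]))))
    return configs


def grid_search(
    X, y, train_ids, test_ids, n_settings: int = 38, seed: int = 0,
    grid_domain: dict = None, base: SRConfig = None,
) -> list:
    """Run the settings study: one SR run per sampled grid point.

    Results come back ordered by the overfit measure TEE - TRE (ascending),
    each run seeded independently but reproducibly from ``seed``.
    """
    configs = sample_grid_configs(n_settings, seed, grid_domain, base)
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=len(configs))
    results = []
    for cfg, s in zip(configs, run_seeds):
        results.append(run_sr(X, y, train_ids, test_ids, replace(cfg, seed=int(s))))
    return sorted(results, key=lambda r: r.overfit)


def overfit_delta(run_imputed: SRRunResult, run_complete: SRRunResult) -> float:
    """|overfit_imputed - overfit_complete| for matched runs."""
    if run_imputed.config.grid_point() != run_complete.config.grid_point():
        raise ValueError("runs must share the same hyper-parameter setting")
    if (run_imputed.train_ids, run_imputed.test_ids) != (
        run_complete.train_ids, run_complete.test_ids,
    ):
        raise ValueError("runs must share the same train/test split")
    return abs(run_imputed.overfit - run_complete.overfit)


def repeated_runs(
    X, y, train_ids, test_ids, config: SRConfig, n_runs: int = 50, seed: int = 0
):
    """Repeat training with fresh seeds and tally parameter recurrence.

    The evolutionary search is stochastic, so individual models differ
    between runs; counting how often each parameter features in the final
    models reveals which parameters the search consistently finds useful.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    results = [
        run_sr(X, y, train_ids, test_ids, replace(config, seed=int(s))) for s in run_seeds
    ]
    counts = {name: 0 for name in X.columns}
    for res in results:
        for p in res.model.used_parameters:
            counts[p] += 1
    return results, RecurrenceTable(counts, n_runs)


def press_cv(
    variants: dict, config: SRConfig, n_splits: int = 10,
    holdout_fraction: float = 1 / 3, seed: int = 0,
) -> pd.DataFrame:
    """PRESS-style cross-validation across dataset variants.

    For each variant ``name -> (X, y)``, models are trained on ``n_splits``
    resampled splits; squared prediction residuals on the held-out rows
    accumulate into a PRESS statistic.  R^2 = 1 - PRESS/SST (SST over the
    pooled held-out responses) and adjusted
    R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1) with p = mean gene count + 1;
    when n - p - 1 <= 0 the adjusted value is undefined (NaN).
    """
    if len(variants) < 2:
        raise ValueError("need at least 2 dataset variants to compare")
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(0, 2**31 - 1, size=n_splits)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_splits)
    rows = []
    for name, (X, y) in variants.items():
        press = 0.0
        held_y = []
        held_pred = []
        gene_counts = []
        for s_split, s_run in zip(split_seeds, run_seeds):
            train_ids, test_ids = split_train_test(list(X.index), 1 - holdout_fraction, int(s_split))
            res = run_sr(X, y, train_ids, test_ids, replace(config, seed=int(s_run)))
            pred = res.model.predict(X.loc[test_ids])
            held_y.append(y.loc[test_ids].to_numpy(dtype=float))
            held_pred.append(pred)
            press += float(np.sum((pred - y.loc[test_ids].to_numpy(dtype=float)) ** 2))
            gene_counts.append(len(res.model.genes))
        held_y = np.concatenate(held_y)
        sst = float(np.sum((held_y - held_y.mean()) ** 2))
        r2 = 1.0 - press / sst if sst > 0 else np.nan
        n = len(X)
        p = float(np.mean(gene_counts)) + 1
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan
        rows.append({"variant": name, "PRESS": press, "r2": r2, "adjusted_r2": adj,
                     "mean_genes": float(np.mean(gene_counts))})
    return pd.DataFrame(rows).set_index("variant")
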