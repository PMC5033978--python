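"""Decay-rate estimation for motor-memory loss during error-clamp blocks.

The memory readout is the trial-by-trial force at peak velocity, averaged for
each participant across the nine assessment blocks that follow adaptation
(each block contributes its 30 within-block positions).  A single exponential

    y = a * exp(b * x) + c,   x = 1..30

is fit to group-averaged series; ``a + c`` is the initial state, ``b`` the
per-trial decay rate and ``c`` the asymptote.  Because nonlinear fits to
single participants are unstable, uncertainty comes from an exhaustive
subsampling bootstrap: all C(15, 12) = 455 twelve-participant subsets of
each group are averaged and fit, giving 455 parameter triples per group.
Pairwise group differences are assessed with a permutation test: on each
bootstrap iteration the 24 selected participants are randomly reassigned to
two pseudo-groups, refit, and the proportion of permutation differences
exceeding the mean bootstrap difference gives the p-value.

The exponential fit uses variable projection: for any fixed ``b`` the model
is linear in (a, c) and solved in closed form, so the fit reduces to a 1-D
profile search over ``b`` (deterministic grid plus bounded refinement),
which is both fast and free of starting-point sensitivity.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

EC_FIT_BLOCKS = tuple(f"EC{i}" for i in range(1, 10))


class DecayFitError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Knobs of the decay analysis."""

    subsample_k: int = 12
    fit_blocks: tuple = EC_FIT_BLOCKS
    block_length: int = 30
    b_bounds: tuple = (-5.0, 0.5)
    b_grid_size: int = 121
    refine_xatol: float = 1e-12
    #: "two-sided": compare |permutation difference| with |mean bootstrap
    #: difference|; "one-sided": literal "larger than the mean difference".
    permutation_rule: str = "two-sided"


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class ECSeries:
    """A participant's averaged 30-point error-clamp force series."""

    values: np.ndarray
    x: np.ndarray = None
    n_imputed: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.x is None:
            self.x = np.arange(1, self.values.size + 1, dtype=float)
        else:
            self.x = np.asarray(self.x, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DecayFitError("error-clamp series contains non-finite values")


@dataclass
class ExpFit:
    """Fitted single-exponential decay y = a*exp(b*x) + c."""

    a: float
    b: float
    c: float
    r2: float
    sse: float
    converged: bool = True

    @property
    def initial_state(self) -> float:
        return self.a + self.c

    @property
    def params(self) -> np.ndarray:
        """(initial state, rate, asymptote) — the compared parameter triple."""
        return np.array([self.initial_state, self.b, self.c])

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * np.exp(self.b * x) + self.c


@dataclass
class BootstrapComparison:
    """Subsampling-bootstrap + permutation comparison of one group pair.

    Parameter order in all triples: (initial state a+c, rate b, asymptote c).
    """

    pair: tuple
    boot_diffs: np.ndarray       # (m, 3)
    perm_diffs: np.ndarray       # (m, 3)
    mean_diff: np.ndarray        # (3,)
    p: np.ndarray                # (3,)
    n_subsets: int
    permutation_rule: str = "two-sided"

    PARAM_NAMES = ("initial_state", "rate", "asymptote")

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "n_subsets": self.n_subsets,
            "permutation_rule": self.permutation_rule,
            "mean_diff": dict(zip(self.PARAM_NAMES, self.mean_diff.tolist())),
            "p": dict(zip(self.PARAM_NAMES, self.p.tolist())),
        }


# --------------------------------------------------------------------------
# series extraction
# --------------------------------------------------------------------------

def participant_ec_series(records: pd.DataFrame, participant: str,
                          blocks: tuple = EC_FIT_BLOCKS,
                          block_length: int = 30) -> ECSeries:
    """Average a participant's clamp force over blocks at each within-block position.

    Element k is the mean over the listed blocks of the force at position k.
    Missing values (failed trials) are imputed with the mean of the same
    within-block position across the remaining blocks; the imputation count
    is recorded on the returned series.
    """
    sub = records[(records["participant"] == participant)
                  & (records["block_label"].isin(blocks))
                  & (records["phase"] == "EC")]
    have = set(sub["block_label"])
    missing = [b for b in blocks if b not in have]
    if missing:
        raise DecayFitError(
            f"participant {participant}: missing assessment block(s) {missing}")
    grid = sub.pivot_table(index="within_block_index", columns="block_label",
                           values="force_at_pv", dropna=False)
    grid = grid.reindex(index=range(1, block_length + 1), columns=list(blocks))
    matrix = grid.to_numpy(dtype=float)
    n_missing = int(np.isnan(matrix).sum())
    if n_missing:
        row_means = np.nanmean(matrix, axis=1, keepdims=True)
        if np.isnan(row_means).any():
            raise DecayFitError(
                f"participant {participant}: a within-block position is "
                "missing in every block; cannot impute")
        matrix = np.where(np.isnan(matrix), row_means, matrix)
        logger.info("participant %s: imputed %d missing clamp trials",
                    participant, n_missing)
    return ECSeries(values=matrix.mean(axis=1), n_imputed=n_missing)


def group_series_matrix(records: pd.DataFrame, group: str,
                        blocks: tuple = EC_FIT_BLOCKS,
                        block_length: int = 30) -> np.ndarray:
    """(n_participants, block_length) matrix of averaged series for one group."""
    participants = sorted(records.loc[records["group"] == group, "participant"].unique())
    if not participants:
        raise DecayFitError(f"no participants in group {group!r}")
    return np.vstack([
        participant_ec_series(records, p, blocks, block_length).values
        for p in participants
    ])


# --------------------------------------------------------------------------
# exponential fitting (variable projection)
# --------------------------------------------------------------------------

def _linear_solve(E: np.ndarray, y: np.ndarray):
    """Closed-form least squares of y on [exp(bx), 1] for rows of E."""
    n = y.size
    s_e = E.sum(axis=-1)
    s_ee = (E * E).sum(axis=-1)
    s_y = y.sum()
    s_ey = E @ y
    det = n * s_ee - s_e * s_e
    bad = np.abs(det) < 1e-12 * n * np.maximum(s_ee, 1.0)
    det = np.where(bad, 1.0, det)
    a = (n * s_ey - s_e * s_y) / det
    c = (s_ee * s_y - s_e * s_ey) / det
    return a, c, bad


def fit_exponential(series, x=None,
                    config: AnalysisConfig | None = None) -> ExpFit:
    """Least-squares fit of y = a*exp(b*x) + c.

    Deterministic: profile sum of squares over a fixed grid of rates,
    followed by bounded scalar refinement in the bracketing interval.  For a
    constant series the rate is unidentifiable; the fit then returns a ~ 0
    with c at the series mean.
    """
    if isinstance(series, ECSeries):
        y, x = series.values, series.x
    else:
        y = np.asarray(series, dtype=float)
        x = np.arange(1, y.size + 1, dtype=float) if x is None else np.asarray(x, dtype=float)
    if y.size < 4:
        raise DecayFitError("need at least 4 points to fit a three-parameter model")
    config = config or AnalysisConfig()

    b_lo, b_hi = config.b_bounds
    grid = np.linspace(b_lo, b_hi, config.b_grid_size)
    E = np.exp(np.outer(grid, x))
    a_g, c_g, bad = _linear_solve(E, y)
    resid = y[None, :] - a_g[:, None] * E - c_g[:, None]
    sse_grid = np.einsum("ij,ij->i", resid, resid)
    sse_grid[bad] = np.inf
    i_best = int(np.argmin(sse_grid))

    def profile_sse(b: float) -> float:
        e = np.exp(b * x)
        a, c, bad1 = _linear_solve(e[None, :], y)
        if bad1[0]:
            return float("inf")
        r = y - a[0] * e - c[0]
        return float(r @ r)

    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, grid.size - 1)]
    res = minimize_scalar(profile_sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": config.refine_xatol})
    candidates = [(sse_grid[i_best], float(grid[i_best]))]
    converged = bool(res.success)
    if converged and np.isfinite(res.fun):
        candidates.append((float(res.fun), float(res.x)))
    sse_best, b_best = min(candidates)

    e = np.exp(b_best * x)
    a, c, bad1 = _linear_solve(e[None, :], y)
    a_best, c_best = float(a[0]), float(c[0])
    if bad1[0]:
        # rate numerically unidentifiable (exp(bx) ~ constant)
        a_best, c_best = 0.0, float(y.mean())
        sse_best = float(((y - c_best) ** 2).sum())
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot > 0:
        r2 = 1.0 - sse_best / sstot
    else:
        r2 = 1.0 if sse_best <= 1e-18 else -math.inf
    return ExpFit(a=a_best, b=b_best, c=c_best, r2=r2, sse=sse_best,
                  converged=converged)


# --------------------------------------------------------------------------
# subsampling bootstrap and permutation inference
# --------------------------------------------------------------------------

def enumerate_subsamples(n: int, k: int) -> list[tuple[int, ...]]:
    """All C(n, k) index subsets in lexicographic order (no randomness)."""
    if not 0 < k <= n:
        raise DecayFitError(f"subset size {k} must satisfy 0 < k <= n = {n}")
    return list(itertools.combinations(range(n), k))


def subsample_fits(series_matrix: np.ndarray, k: int = 12,
                   subsets: list | None = None,
                   config: AnalysisConfig | None = None) -> list[ExpFit]:
    """Fit the pointwise average of every enumerated subset of participants."""
    series_matrix = np.asarray(series_matrix, dtype=float)
    if subsets is None:
        subsets = enumerate_subsamples(series_matrix.shape[0], k)
    return [
        fit_exponential(series_matrix[list(s)].mean(axis=0), config=config)
        for s in subsets
    ]


def permutation_test(pair_a: np.ndarray, pair_b: np.ndarray,
                     rng: np.random.Generator,
                     config: AnalysisConfig | None = None) -> np.ndarray:
    """One random relabeling of the pooled participants into two pseudo-groups.

    Returns the (initial state, rate, asymptote) difference between the
    pseudo-group fits (A-labeled minus B-labeled).
    """
    pooled = np.vstack([pair_a, pair_b])
    n_a = pair_a.shape[0]
    order = rng.permutation(pooled.shape[0])
    fit_a = fit_exponential(pooled[order[:n_a]].mean(axis=0), config=config)
    fit_b = fit_exponential(pooled[order[n_a:]].mean(axis=0), config=config)
    return fit_a.params - fit_b.params


def compare_groups(series_a: np.ndarray, series_b: np.ndarray, seed: int = 0,
                   k: int = 12, max_subsets: int | None = None,
                   labels: tuple = ("A", "B"),
                   config: AnalysisConfig | None = None) -> BootstrapComparison:
    """Full pairwise comparison of two groups of averaged clamp series.

    Subset i of group A is paired with subset i of group B (lexicographic
    order); each iteration contributes one bootstrap difference and one
    permutation difference computed from that iteration's 2k participants.
    ``max_subsets`` randomly thins the enumerated subsets (seeded) for cheap
    replicated experiments.
    """
    config = config or AnalysisConfig()
    series_a = np.asarray(series_a, dtype=float)
    series_b = np.asarray(series_b, dtype=float)
    subsets_a = enumerate_subsamples(series_a.shape[0], k)
    subsets_b = enumerate_subsamples(series_b.shape[0], k)
    m = min(len(subsets_a), len(subsets_b))
    rng = np.random.default_rng([int(seed), 1057])
    if max_subsets is not None and max_subsets < m:
        keep = np.sort(rng.choice(m, size=max_subsets, replace=False))
        subsets_a = [subsets_a[i] for i in keep]
        subsets_b = [subsets_b[i] for i in keep]
        m = max_subsets
    else:
        subsets_a = subsets_a[:m]
        subsets_b = subsets_b[:m]

    boot = np.empty((m, 3))
    perm = np.empty((m, 3))
    for i, (sa, sb) in enumerate(zip(subsets_a, subsets_b)):
        rows_a = series_a[list(sa)]
        rows_b = series_b[list(sb)]
        fa = fit_exponential(rows_a.mean(axis=0), config=config)
        fb = fit_exponential(rows_b.mean(axis=0), config=config)
        boot[i] = fa.params - fb.params
        perm[i] = permutation_test(rows_a, rows_b, rng, config=config)

    mean_diff = boot.mean(axis=0)
    if config.permutation_rule == "two-sided":
        p = (np.abs(perm) > np.abs(mean_diff)).mean(axis=0)
    elif config.permutation_rule == "one-sided":
        p = (perm > mean_diff).mean(axis=0)
    else:
        raise DecayFitError(f"unknown permutation rule {config.permutation_rule!r}")
    return BootstrapComparison(pair=tuple(labels), boot_diffs=boot,
                               perm_diffs=perm, mean_diff=mean_diff, p=p,
                               n_subsets=m,
                               permutation_rule=config.permutation_rule)


# --------------------------------------------------------------------------
# model / results objects
# --------------------------------------------------------------------------

@dataclass
class GroupDecayFit:
    """Per-group decay estimate: grand-average fit plus subsample distribution."""

    group: str
    grand_fit: ExpFit
    subsample_params: np.ndarray    # (m, 3): initial state, rate, asymptote
    subsample_r2: np.ndarray
    n_participants: int
    n_subsets: int

    @property
    def params_mean(self) -> np.ndarray:
        return self.subsample_params.mean(axis=0)

    @property
    def params_sd(self) -> np.ndarray:
        return self.subsample_params.std(axis=0, ddof=1)

    def to_dict(self) -> dict:
        names = BootstrapComparison.PARAM_NAMES
        return {
            "group": self.group,
            "n_participants": self.n_participants,
            "n_subsets": self.n_subsets,
            "grand_fit": {"a": self.grand_fit.a, "b": self.grand_fit.b,
                          "c": self.grand_fit.c, "r2": self.grand_fit.r2,
                          "initial_state": self.grand_fit.initial_state},
            "subsample_mean": dict(zip(names, self.params_mean.tolist())),
            "subsample_sd": dict(zip(names, self.params_sd.tolist())),
            "r2_min": float(self.subsample_r2.min()),
            "r2_mean": float(self.subsample_r2.mean()),
        }


class CohortDecayModel:
    """Decay-rate model for a cohort trial table.

    Parameters
    ----------
    records : DataFrame
        Long-format trial table with at least the columns group,
        participant, phase, block_label, within_block_index, force_at_pv.
    groups : sequence of str, optional
        Groups to analyze (defaults to those present, sorted).
    config : AnalysisConfig, optional

    ``fit`` runs the exponential fits, the exhaustive subsampling bootstrap
    and the pairwise permutation tests, and returns a
    :class:`CohortDecayResults`.
    """

    def __init__(self, records: pd.DataFrame, groups=None,
                 config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        self.groups = tuple(groups) if groups is not None else tuple(
            sorted(records["group"].unique()))
        if not self.groups:
            raise DecayFitError("no groups to analyze")
        self.series = {
            g: group_series_matrix(records, g, self.config.fit_blocks,
                                   self.config.block_length)
            for g in self.groups
        }

    @classmethod
    def from_series(cls, series_by_group: dict,
                    config: AnalysisConfig | None = None) -> "CohortDecayModel":
        """Build directly from {group: (n_participants, block_length) array}."""
        model = cls.__new__(cls)
        model.config = config or AnalysisConfig()
        model.groups = tuple(series_by_group)
        model.series = {g: np.asarray(v, dtype=float)
                        for g, v in series_by_group.items()}
        return model

    def fit(self, seed: int = 0, max_subsets: int | None = None) -> "CohortDecayResults":
        cfg = self.config
        group_fits = {}
        for g, matrix in self.series.items():
            fits = subsample_fits(matrix, cfg.subsample_k, config=cfg)
            group_fits[g] = GroupDecayFit(
                group=g,
                grand_fit=fit_exponential(matrix.mean(axis=0), config=cfg),
                subsample_params=np.array([f.params for f in fits]),
                subsample_r2=np.array([f.r2 for f in fits]),
                n_participants=matrix.shape[0],
                n_subsets=len(fits),
            )
        comparisons = {}
        for ga, gb in itertools.combinations(self.groups, 2):
            comparisons[(ga, gb)] = compare_groups(
                self.series[ga], self.series[gb], seed=seed,
                k=cfg.subsample_k, max_subsets=max_subsets,
                labels=(ga, gb), config=cfg)
        return CohortDecayResults(model=self, group_fits=group_fits,
                                  comparisons=comparisons, seed=seed)


@dataclass
class CohortDecayResults:
    """Estimates, subsample distributions and pairwise inference for a cohort."""

    model: CohortDecayModel
    group_fits: dict
    comparisons: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "groups": {g: f.to_dict() for g, f in self.group_fits.items()},
            "comparisons": [c.to_dict() for c in self.comparisons.values()],
        }

    def boot_perm_frame(self) -> pd.DataFrame:
        """Long-format bootstrap/permutation difference samples (CSV export)."""
        rows = []
        names = BootstrapComparison.PARAM_NAMES
        for (ga, gb), comp in self.comparisons.items():
            for kind, arr in (("bootstrap", comp.boot_diffs),
                              ("permutation", comp.perm_diffs)):
                for it in range(arr.shape[0]):
                    for j, name in enumerate(names):
                        rows.append({"group_a": ga, "group_b": gb,
                                     "kind": kind, "iteration": it + 1,
                                     "parameter": name, "difference": arr[it, j]})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary: per-group parameters and pairwise p-values."""
        lines = ["Motor-memory decay: exponential fit y = a*exp(b*x) + c",
                 ""]
        lines.append(f"{'group':<12}{'a+c':>10}{'b':>10}{'c':>10}"
                     f"{'sd(b)':>10}{'min r2':>9}{'n_sub':>7}")
        for g, f in self.group_fits.items():
            m, sd = f.params_mean, f.params_sd
            lines.append(
                f"{g:<12}{m[0]:>10.3f}{m[1]:>10.3f}{m[2]:>10.3f}"
                f"{sd[1]:>10.3f}{f.subsample_r2.min():>9.3f}{f.n_subsets:>7d}")
        lines.append("")
        lines.append(f"{'pairwise comparison':<28}{'p(a+c)':>9}{'p(b)':>9}{'p(c)':>9}")
        for (ga, gb), comp in self.comparisons.items():
            lines.append(f"{ga + ' vs. ' + gb:<28}"
                         f"{comp.p[0]:>9.4f}{comp.p[1]:>9.4f}{comp.p[2]:>9.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Group-mean clamp series with fitted exponentials."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g, matrix in self.model.series.items():
            mean = matrix.mean(axis=0)
            x = np.arange(1, mean.size + 1)
            line, = ax.plot(x, mean, "o", ms=3, label=g)
            ax.plot(x, self.group_fits[g].grand_fit.predict(x),
                    color=line.get_color())
        ax.set_xlabel("error-clamp trial position")
        ax.set_ylabel("force at peak velocity (N s/m)")
        ax.legend()
        return ax
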