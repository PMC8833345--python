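"""Cause-of-death modelling by component-wise gradient boosting with
decision stumps, and permutation-null significance of per-level effects.

The model is an additive logistic ("generalized linear") model built by
functional gradient descent on the binomial negative log-likelihood:
starting from the sample log-odds, each iteration fits one depth-one
regression tree (a stump splitting a single categorical predictor into
one level versus the rest) to the current negative gradient, picks the
best-fitting stump across all predictors, and adds it scaled by the step
length nu. After ``mstop`` iterations each predictor level carries an
additive log-odds contribution toward death due to the tumor (outcome 1)
versus death due to another cause (outcome 0).

Because boosting effects have no closed-form reference distribution,
significance is assessed against a permutation null: the outcome vector
is shuffled B times, the whole model refit, and every level's observed
effect compared two-sidedly against its own null distribution of effects,
with the add-one (never-zero) p-value estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import CaseRecord, RegistryBundle, METASTASIS, SEXES, TREATMENTS

PREDICTORS = (
    "metastasis",
    "type_of_neoplasm",
    "tumor_type",
    "n_tumor_types",
    "treatment",
    "family",
    "species",
    "sex",
)


@dataclass
class OutcomeDesign:
    """Encoded modelling design: one row per snake with a known cause of
    death; outcome 1 = died/euthanized due to the neoplasm."""

    y: np.ndarray  # (n,) 0/1
    codes: np.ndarray  # (n, P) globally-offset integer level codes
    predictor_names: tuple[str, ...]
    level_names: tuple[str, ...]  # (L,) global level vocabulary
    level_predictor: np.ndarray  # (L,) predictor index of each level
    offsets: np.ndarray  # (P+1,) level-code range of each predictor
    case_ids: tuple[str, ...]
    sampling_seed: int

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_levels(self) -> int:
        return len(self.level_names)

    def level_counts(self) -> np.ndarray:
        return np.bincount(self.codes.ravel(), minlength=self.n_levels)


@dataclass(frozen=True)
class BoostConfig:
    nu: float = 0.1  # step length
    mstop: int = 100  # boosting iterations
    stump: str = "level_vs_rest"  # or "two_subset"
    selection: str = "sse"  # split-choice criterion; or "standardized"
    minbucket: int = 4  # smallest group size a split may create
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.nu <= 1:
            raise ValueError("nu must lie in (0, 1]")
        if self.mstop < 1:
            raise ValueError("mstop must be >= 1")
        if self.stump not in ("level_vs_rest", "two_subset"):
            raise ValueError(f"unknown stump form {self.stump!r}")
        if self.selection not in ("standardized", "sse"):
            raise ValueError(f"unknown selection criterion {self.selection!r}")
        if self.minbucket < 1:
            raise ValueError("minbucket must be >= 1")


@dataclass
class BoostModel:
    intercept: float
    contributions: np.ndarray  # (L,) accumulated additive log-odds per level
    training_loss_path: np.ndarray  # (mstop,) mean binomial NLL
    design: OutcomeDesign
    config: BoostConfig


@dataclass
class PermutationResult:
    table: pd.DataFrame  # predictor, level, sample_size, observed_effect, p, significant
    null_effects: np.ndarray = field(repr=False)  # (B, L_observed)
    B: int = 0

    def significant_levels(self) -> set[tuple[str, str]]:
        sig = self.table[self.table["significant"]]
        return set(zip(sig["predictor"], sig["level"]))


# ---------------------------------------------------------------------------
# Design construction

def _vocab(values) -> list[str]:
    return sorted(set(values))


def build_design(cases: list[CaseRecord], seed: int = 0) -> OutcomeDesign:
    """Encode eligible cases (known cause of death) for boosting.

    For snakes with two tumor types, one (tumor_type, behavior) pair is
    retained by seeded uniform sampling among the tumors of determined
    behavior; snakes with only unspecified-behavior tumors cannot enter
    the type-of-neoplasm tally and are dropped.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[CaseRecord, object]] = []
    for c in cases:
        if not c.eligible_for_outcome_model:
            continue
        determined = [t for t in c.tumors if t.behavior != "unspecified"]
        if not determined:
            continue
        rows.append((c, determined[rng.integers(len(determined))]))
    if not rows:
        raise ValueError("no eligible cases for outcome modelling")

    vocab = {
        "metastasis": list(METASTASIS),
        "type_of_neoplasm": ["malignant", "benign"],
        "tumor_type": _vocab(t.tumor_type for c, _ in rows for t in c.tumors),
        "n_tumor_types": ["1", "2"],
        "treatment": list(TREATMENTS),
        "family": _vocab(c.family for c, _ in rows),
        "species": _vocab(c.species for c, _ in rows),
        "sex": list(SEXES),
    }

    def values(c: CaseRecord, t) -> dict[str, str]:
        return {
            "metastasis": c.metastasis,
            "type_of_neoplasm": t.behavior,
            "tumor_type": t.tumor_type,
            "n_tumor_types": str(c.n_tumor_types),
            "treatment": c.treatment,
            "family": c.family,
            "species": c.species,
            "sex": c.sex,
        }

    offsets = np.zeros(len(PREDICTORS) + 1, dtype=np.int64)
    level_names: list[str] = []
    level_predictor: list[int] = []
    index: dict[tuple[str, str], int] = {}
    for j, name in enumerate(PREDICTORS):
        for lev in vocab[name]:
            index[(name, lev)] = len(level_names)
            level_names.append(lev)
            level_predictor.append(j)
        offsets[j + 1] = len(level_names)

    codes = np.empty((len(rows), len(PREDICTORS)), dtype=np.int64)
    for i, (c, t) in enumerate(rows):
        vals = values(c, t)
        for j, name in enumerate(PREDICTORS):
            codes[i, j] = index[(name, vals[name])]

    y = np.array([1 if c.outcome == "died_of_tumor" else 0 for c, _ in rows],
                 dtype=np.int8)
    return OutcomeDesign(
        y=y,
        codes=codes,
        predictor_names=PREDICTORS,
        level_names=tuple(level_names),
        level_predictor=np.asarray(level_predictor, dtype=np.int64),
        offsets=offsets,
        case_ids=tuple(c.case_id for c, _ in rows),
        sampling_seed=seed,
    )


def design_from_bundle(bundle: RegistryBundle, seed: int = 0) -> OutcomeDesign:
    return build_design(bundle.cases, seed=seed)


def design_from_frame(frame: pd.DataFrame, y) -> OutcomeDesign:
    """Encode an arbitrary all-categorical DataFrame plus a 0/1 outcome
    vector as an :class:`OutcomeDesign` (for simulations and tests)."""
    y = np.asarray(y, dtype=np.int8)
    if len(frame) != len(y):
        raise ValueError("frame and outcome lengths differ")
    names = tuple(str(c) for c in frame.columns)
    offsets = np.zeros(len(names) + 1, dtype=np.int64)
    level_names: list[str] = []
    level_predictor: list[int] = []
    codes = np.empty((len(frame), len(names)), dtype=np.int64)
    for j, col in enumerate(frame.columns):
        values = frame[col].astype(str).to_numpy()
        levels = sorted(set(values))
        lookup = {lev: offsets[j] + k for k, lev in enumerate(levels)}
        codes[:, j] = [lookup[v] for v in values]
        level_names.extend(levels)
        level_predictor.extend([j] * len(levels))
        offsets[j + 1] = len(level_names)
    return OutcomeDesign(
        y=y,
        codes=codes,
        predictor_names=names,
        level_names=tuple(level_names),
        level_predictor=np.asarray(level_predictor, dtype=np.int64),
        offsets=offsets,
        case_ids=tuple(str(i) for i in range(len(frame))),
        sampling_seed=0,
    )


# ---------------------------------------------------------------------------
# Boosting

def _fit_arrays(y, codes, design: OutcomeDesign, config: BoostConfig):
    """Core loop over (possibly permuted) outcome y; returns
    (intercept, contributions, loss path)."""
    n, P = codes.shape
    L = design.n_levels
    ybar = float(np.mean(y))
    if ybar in (0.0, 1.0):
        raise ValueError("degenerate model: only one outcome class present")
    intercept = float(np.log(ybar / (1.0 - ybar)))

    flat = codes.T.ravel()  # column-major level codes, length P*n
    counts = np.bincount(flat, minlength=L).astype(np.float64)
    rest = n - counts
    mb = config.minbucket
    valid = (counts >= mb) & (rest >= mb)
    two_subset = config.stump == "two_subset"
    pred_df = np.array(
        [
            int((counts[design.offsets[k]: design.offsets[k + 1]] > 0).sum()) - 1
            for k in range(len(design.predictor_names))
        ]
    )

    valid_pred = np.array(
        [
            bool(valid[design.offsets[k]: design.offsets[k + 1]].any())
            for k in range(len(design.predictor_names))
        ]
    )

    F = np.full(n, intercept)
    contrib = np.zeros(L)
    yf = y.astype(np.float64)
    loss0 = (np.logaddexp(0.0, F).sum() - yf @ F) / n
    losses = np.full(config.mstop, loss0)
    if not two_subset and not valid_pred.any():
        # no admissible split anywhere: the model stays at the intercept
        return intercept, contrib, losses

    for m in range(config.mstop):
        p = 1.0 / (1.0 + np.exp(-F))
        g = yf - p  # negative gradient of the binomial NLL
        S = g.sum()
        s = np.bincount(flat, weights=np.tile(g, P), minlength=L)

        if not two_subset:
            u = np.zeros(L)
            u[valid] = (s[valid] - counts[valid] * S / n) ** 2 / counts[valid]
            if config.selection == "standardized":
                # conditional-inference style variable selection: each
                # predictor's levels enter a quadratic association
                # statistic (chi-square with #levels-1 df under the
                # permutation distribution), and the predictor with the
                # smallest p wins, so many-level predictors cannot claim
                # splits on tiny noisy levels for free
                sigma2 = max(float(np.mean((g - S / n) ** 2)), 1e-300)
                q = np.add.reduceat(u, design.offsets[:-1]) * (n - 1) / (n * sigma2)
                k = np.maximum(pred_df, 1)
                # Wilson-Hilferty normalization: monotone in the
                # chi-square upper-tail p across different df
                z = ((q / k) ** (1.0 / 3.0) - (1.0 - 2.0 / (9.0 * k))) / np.sqrt(
                    2.0 / (9.0 * k)
                )
                z[~valid_pred] = -np.inf
                j = int(np.argmax(z))
            else:
                # raw best-gain selection: predictor owning the single
                # level-vs-rest split with the best squared-error fit
                gain = np.where(valid, u * n / np.maximum(rest, 1), -np.inf)
                j = int(design.level_predictor[int(np.argmax(gain))])
            lo_j, hi_j = design.offsets[j], design.offsets[j + 1]
            within = np.where(
                valid[lo_j:hi_j], u[lo_j:hi_j] * n / np.maximum(rest[lo_j:hi_j], 1),
                -np.inf,
            )
            lev = int(lo_j + np.argmax(within))
            in_split = codes[:, j] == lev
            members = np.array([lev])
        else:
            j, members = _best_two_subset(s, counts, design, S, n, mb)
            if len(members) == 0:  # no admissible two-subset cut
                losses[m:] = losses[m - 1] if m else loss0
                break
            in_split = np.isin(codes[:, j], members)

        n_in = counts[members].sum() if two_subset else counts[lev]
        s_in = s[members].sum() if two_subset else s[lev]
        a = s_in / n_in
        b = (S - s_in) / (n - n_in)
        F += config.nu * np.where(in_split, a, b)
        lo, hi = design.offsets[j], design.offsets[j + 1]
        contrib[lo:hi] += config.nu * b
        contrib[members] += config.nu * (a - b)
        losses[m] = (np.logaddexp(0.0, F).sum() - yf @ F) / n

    return intercept, contrib, losses


def _best_two_subset(s, counts, design, S, n, minbucket=1):
    """Best split of one predictor's levels into two groups: levels are
    ordered by mean gradient and the best admissible contiguous cut taken
    (optimal for squared error)."""
    best = (-np.inf, 0, np.empty(0, dtype=np.int64))
    for j in range(len(design.predictor_names)):
        lo, hi = design.offsets[j], design.offsets[j + 1]
        idx = np.arange(lo, hi)[counts[lo:hi] > 0]
        if len(idx) < 2:
            continue
        order = idx[np.argsort(s[idx] / counts[idx])]
        cs = np.cumsum(s[order])
        cn = np.cumsum(counts[order])
        left_n, left_s = cn[:-1], cs[:-1]
        ok = (left_n >= minbucket) & (n - left_n >= minbucket)
        if not ok.any():
            continue
        gain = np.where(
            ok, left_s ** 2 / left_n + (S - left_s) ** 2 / (n - left_n), -np.inf
        )
        k = int(np.argmax(gain))
        if gain[k] > best[0]:
            best = (float(gain[k]), j, order[: k + 1])
    return best[1], best[2]


def fit_boost(design: OutcomeDesign, config: BoostConfig | None = None) -> BoostModel:
    """Fit the boosted stump model; training loss is checked to be
    non-increasing across iterations."""
    config = config or BoostConfig()
    intercept, contrib, losses = _fit_arrays(design.y, design.codes, design, config)
    if np.any(np.diff(losses) > 1e-9):
        raise AssertionError("training loss increased during boosting")
    return BoostModel(
        intercept=intercept,
        contributions=contrib,
        training_loss_path=losses,
        design=design,
        config=config,
    )


def _centered_effects(contrib: np.ndarray, design: OutcomeDesign,
                      counts: np.ndarray) -> np.ndarray:
    """Center contributions within each predictor so the observation-
    count-weighted mean is zero; levels unseen in the design are zeroed."""
    eff = contrib.copy()
    for j in range(len(design.predictor_names)):
        lo, hi = design.offsets[j], design.offsets[j + 1]
        w = counts[lo:hi]
        if w.sum() > 0:
            eff[lo:hi] -= (w * eff[lo:hi]).sum() / w.sum()
    eff[counts == 0] = 0.0
    return eff


def extract_effects(model: BoostModel, design: OutcomeDesign | None = None) -> pd.DataFrame:
    """Per-(predictor, level) centered additive log-odds effects with
    sample sizes; only levels present in the design are reported."""
    design = design or model.design
    counts = design.level_counts()
    eff = _centered_effects(model.contributions, design, counts)
    rows = [
        {
            "predictor": design.predictor_names[design.level_predictor[l]],
            "level": design.level_names[l],
            "sample_size": int(counts[l]),
            "outcome_effect": float(eff[l]),
        }
        for l in range(design.n_levels)
        if counts[l] > 0
    ]
    return pd.DataFrame(rows, columns=["predictor", "level", "sample_size", "outcome_effect"])


# ---------------------------------------------------------------------------
# Permutation-null significance

def permutation_test(
    design: OutcomeDesign,
    config: BoostConfig | None = None,
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    design_factory=None,
) -> PermutationResult:
    """Compare each level's observed effect against B refits on uniformly
    permuted outcomes (two-sided, add-one p-value: p >= 1/(B+1)).

    ``design_factory(rng)``, if given, supplies a fresh design per
    permutation (re-drawing the multi-tumor sampling) whose outcome is
    then permuted; by default the tumor sampling stays fixed and only the
    outcome vector is shuffled.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    config = config or BoostConfig()
    rng = np.random.default_rng(seed)

    model = fit_boost(design, config)
    counts = design.level_counts()
    observed = _centered_effects(model.contributions, design, counts)
    keep = np.flatnonzero(counts > 0)

    null = np.empty((B, len(keep)))
    for b in range(B):
        d = design if design_factory is None else design_factory(rng)
        y_perm = rng.permutation(d.y)
        _, contrib, _ = _fit_arrays(y_perm, d.codes, d, config)
        eff = _centered_effects(contrib, d, d.level_counts())
        null[b] = eff[keep]

    obs = observed[keep]
    exceed = (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)
    p = (1.0 + exceed) / (B + 1.0)

    table = pd.DataFrame(
        {
            "predictor": [design.predictor_names[design.level_predictor[l]] for l in keep],
            "level": [design.level_names[l] for l in keep],
            "sample_size": counts[keep].astype(int),
            "observed_effect": obs,
            "p_two_sided": p,
            "significant": p < alpha,
        }
    )
    return PermutationResult(table=table, null_effects=null, B=B)


def run_outcome_pipeline(
    bundle: RegistryBundle,
    config: BoostConfig | None = None,
    B: int = 2000,
    seed: int = 0,
    resample_per_permutation: bool = False,
) -> tuple[pd.DataFrame, PermutationResult]:
    """Full pipeline: design construction (multi-tumor sampling from the
    run seed), boosting fit, effect extraction and permutation test."""
    config = config or BoostConfig()
    design = build_design(bundle.cases, seed=seed)
    model = fit_boost(design, config)
    effects = extract_effects(model, design)
    factory = None
    if resample_per_permutation:
        def factory(rng):
            return build_design(bundle.cases, seed=int(rng.integers(2**31 - 1)))
    perm = permutation_test(
        design, config, B=B, seed=seed + 1, design_factory=factory
    )
    return effects, perm


__all__ = [
    "PREDICTORS", "OutcomeDesign", "BoostConfig", "BoostModel",
    "PermutationResult", "build_design", "design_from_bundle",
    "fit_boost", "extract_effects", "permutation_test", "run_outcome_pipeline",
]
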