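"""Linear QSAR of log relative binding affinity from interaction fingerprints.

The model is

    log RBA = sum_i c_i FP_i + C

where FP1..FP4 are binary interaction bits (Asp351 salt bridge; Glu353,
His524 and Thr347 hydrogen bonds), FP5 is the ligand internal hydrogen-bond
count and FP6 the hydrophobic contact score log P_C.  RBA is the relative
binding affinity on the percent scale where 17beta-estradiol = 100, so the
intercept is the affinity of a ligand making no scored interaction.

``published_model`` ships the reported coefficient set; ``fit_mlr`` /
``loo_q2`` / ``ga_select`` retrain models by ordinary least squares with
leave-one-out validation and genetic-algorithm feature selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from hydroqsar.pharmacophore import FeatureHit

FP_NAMES = ("FP1", "FP2", "FP3", "FP4", "FP5", "FP6")

# Candidate-feature order used by GA selection (the six modeled bits plus the
# three computable-but-unscored candidates).
CANDIDATE_NAMES = FP_NAMES + ("Leu346_hb", "Arg394_acc", "Phe404_stack")

_FEATURE_TO_BIT = {
    "salt_bridge_D351": "FP1",
    "hb_E353": "FP2",
    "hb_H524": "FP3",
    "hb_T347": "FP4",
    "hb_L346": "Leu346_hb",
    "hb_R394": "Arg394_acc",
    "pistack_F404": "Phe404_stack",
}


@dataclass
class InteractionFingerprint:
    """The FP1..FP6 interaction vector with provenance of each set bit."""

    FP1: int = 0
    FP2: int = 0
    FP3: int = 0
    FP4: int = 0
    FP5: int = 0
    FP6: float = 0.0
    candidate_bits: dict[str, float] = field(default_factory=dict)
    provenance: list[FeatureHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("FP1", "FP2", "FP3", "FP4"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be binary")
        if self.FP5 < 0 or int(self.FP5) != self.FP5:
            raise ValueError("FP5 must be a non-negative integer")
        if self.FP6 < 0:
            raise ValueError("FP6 (log P_C) must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.FP1, self.FP2, self.FP3, self.FP4,
                         self.FP5, self.FP6], float)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FP_NAMES, self.as_array()))


@dataclass
class QsarModel:
    """Linear model: per-feature coefficients, intercept and diagnostics."""

    coefficients: dict[str, float]
    intercept: float
    feature_mask: tuple[str, ...] = FP_NAMES
    r2: float | None = None
    q2: float | None = None
    n: int | None = None
    stderr: dict[str, float] | None = None

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[f] for f in self.feature_mask])


@dataclass
class Prediction:
    """Predicted log RBA with the per-feature contribution breakdown."""

    log_rba: float
    per_feature_contribution: dict[str, float]
    intercept: float

    @property
    def rba(self) -> float:
        return 10.0 ** self.log_rba


def published_model() -> QsarModel:
    """The reported six-feature model (coefficients and intercept verbatim)."""
    return QsarModel(
        coefficients={"FP1": 0.923, "FP2": 2.209, "FP3": 1.689,
                      "FP4": 1.487, "FP5": 0.614, "FP6": 3.861},
        intercept=-9.341,
        feature_mask=FP_NAMES,
        r2=0.96, q2=0.93, n=31,
    )


def build_fingerprint(hits: list[FeatureHit],
                      logpc: float) -> InteractionFingerprint:
    """Map detected feature hits plus log P_C onto the fingerprint."""
    fp = InteractionFingerprint(FP6=float(logpc))
    for h in hits:
        bit = _FEATURE_TO_BIT.get(h.feature)
        if bit in ("FP1", "FP2", "FP3", "FP4"):
            setattr(fp, bit, 1)
        elif bit is not None:
            fp.candidate_bits[bit] = 1.0
        elif h.feature == "internal_hb":
            fp.FP5 = int(h.measured.get("count", 1))
    fp.provenance = list(hits)
    return fp


def predict_log_rba(fp: InteractionFingerprint,
                    model: QsarModel | None = None) -> Prediction:
    """Score a fingerprint: log RBA = C + sum_i c_i FP_i."""
    model = model or published_model()
    values = {**fp.as_dict(), **fp.candidate_bits}
    contributions = {}
    for name in model.feature_mask:
        if name not in values:
            raise ValueError(f"fingerprint missing model feature {name!r}")
        contributions[name] = model.coefficients[name] * values[name]
    log_rba = model.intercept + sum(contributions.values())
    return Prediction(log_rba=log_rba,
                      per_feature_contribution=contributions,
                      intercept=model.intercept)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _design(X: np.ndarray, mask_idx: list[int]) -> np.ndarray:
    return np.column_stack([X[:, mask_idx], np.ones(len(X))])


def _resolve_mask(X: np.ndarray, mask, names) -> tuple[list[int], tuple[str, ...]]:
    if names is None:
        names = [f"FP{i+1}" for i in range(X.shape[1])]
    if mask is None:
        idx = list(range(X.shape[1]))
    elif all(isinstance(m, (bool, np.bool_)) for m in mask) and len(mask) == X.shape[1]:
        idx = [i for i, m in enumerate(mask) if m]
    elif all(isinstance(m, str) for m in mask):
        idx = [list(names).index(m) for m in mask]
    else:
        idx = [int(m) for m in mask]
    return idx, tuple(names[i] for i in idx)


def fit_mlr(X: np.ndarray, y: np.ndarray, mask=None,
            feature_names=None) -> QsarModel:
    """Ordinary least squares on the selected feature subset.

    Raises on rank-deficient designs, naming the collinear columns.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    idx, sel_names = _resolve_mask(X, mask, feature_names)
    if len(y) <= len(idx) + 1:
        raise ValueError(
            f"need more than {len(idx) + 1} observations to fit "
            f"{len(idx)} features")
    D = _design(X, idx)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        bad = [sel_names[i] for i in range(len(idx))
               if np.ptp(X[:, idx[i]]) == 0]
        raise ValueError(
            "rank-deficient design (collinear or constant features: "
            f"{bad or sel_names})")
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    pred = D @ beta
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = len(y) - D.shape[1]
    sigma2 = ss_res / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(D.T @ D)
    se = np.sqrt(np.diag(cov))
    return QsarModel(
        coefficients={n: float(b) for n, b in zip(sel_names, beta[:-1])},
        intercept=float(beta[-1]),
        feature_mask=sel_names, r2=r2, n=len(y),
        stderr={**{n: float(s) for n, s in zip(sel_names, se[:-1])},
                "intercept": float(se[-1])})


def loo_q2(X: np.ndarray, y: np.ndarray, mask=None,
           feature_names=None) -> float:
    """Leave-one-out cross-validated Q^2 = 1 - PRESS/TSS.

    Each observation is predicted by the OLS model refit on the other n-1.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    idx, _ = _resolve_mask(X, mask, feature_names)
    n = len(y)
    if n < len(idx) + 2:
        raise ValueError("too few observations for leave-one-out validation")
    D = _design(X, idx)
    # hat-matrix identity: e_loo = residual / (1 - leverage)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise ValueError("rank-deficient design in cross-validation")
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    H = D @ np.linalg.pinv(D.T @ D) @ D.T
    lev = np.diag(H)
    if np.any(lev >= 1.0 - 1e-12):
        raise ValueError("leave-one-out undefined: leverage-1 observation")
    press = float(np.sum((resid / (1.0 - lev)) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def _parsimony_pick(scores: dict[tuple[int, ...], float],
                    tol: float) -> tuple[int, ...]:
    """Among evaluated masks, the smallest one whose Q^2 is within ``tol``
    of the best (ties broken lexicographically)."""
    best = max(scores.values())
    candidates = [m for m, q in scores.items() if q >= best - tol]
    candidates.sort(key=lambda m: (len(m), m))
    return candidates[0]


def exhaustive_select(X: np.ndarray, y: np.ndarray, feature_names=None,
                      parsimony_tol: float = 0.01
                      ) -> tuple[tuple[str, ...], QsarModel]:
    """Best feature subset by LOO Q^2 over all non-empty masks.

    Subsets within ``parsimony_tol`` of the top Q^2 count as ties, resolved
    toward fewer features (then lexicographic order): a chance sliver of
    cross-validated fit never justifies an extra feature.
    """
    X = np.asarray(X, float)
    names = (tuple(feature_names) if feature_names is not None
             else tuple(f"FP{i+1}" for i in range(X.shape[1])))
    scores: dict[tuple[int, ...], float] = {}
    for k in range(1, X.shape[1] + 1):
        for combo in itertools.combinations(range(X.shape[1]), k):
            try:
                scores[combo] = loo_q2(X, y, mask=list(combo),
                                       feature_names=names)
            except ValueError:
                continue
    if not scores:
        raise ValueError("no feasible feature subset")
    combo = _parsimony_pick(scores, parsimony_tol)
    model = fit_mlr(X, y, mask=list(combo), feature_names=names)
    model.q2 = scores[combo]
    return tuple(names[i] for i in combo), model


@dataclass(frozen=True)
class GaConfig:
    """Genetic-algorithm settings for feature-subset selection."""

    population: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 1.0 / 9.0
    elitism: int = 1
    seed: int = 0
    parsimony_tol: float = 0.01

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be at least 2")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")


def ga_select(X: np.ndarray, y: np.ndarray,
              config: GaConfig | None = None,
              feature_names=None) -> tuple[tuple[str, ...], QsarModel]:
    """GA-MLR feature selection: subsets scored by LOO Q^2, near-ties
    (within ``parsimony_tol``) resolved toward fewer features; deterministic
    given the config seed.

    Binary chromosomes over the candidate bits evolve by uniform crossover,
    bit-flip mutation and elitist truncation; the winning mask (chosen with
    the parsimony rule over every subset the search evaluated) is refit on
    the full data.  With zero generations the best of the random initial
    population is returned.
    """
    config = config or GaConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    names = (tuple(feature_names) if feature_names is not None
             else tuple(f"FP{i+1}" for i in range(X.shape[1])))
    nbits = X.shape[1]
    rng = np.random.default_rng(config.seed)

    cache: dict[tuple[int, ...], float] = {}

    def fitness(mask: np.ndarray) -> tuple[float, int]:
        key = tuple(int(b) for b in mask)
        if sum(key) == 0:
            return (-np.inf, nbits + 1)
        if key not in cache:
            try:
                cache[key] = loo_q2(X, y, mask=[i for i, b in enumerate(key)
                                                if b], feature_names=names)
            except ValueError:
                cache[key] = -np.inf
        return (cache[key], -sum(key))

    pop = rng.integers(0, 2, size=(config.population, nbits))
    for row in pop:
        if row.sum() == 0:
            row[rng.integers(nbits)] = 1

    def sort_pop(p: np.ndarray) -> np.ndarray:
        scored = sorted(range(len(p)),
                        key=lambda i: (fitness(p[i])[0], fitness(p[i])[1],
                                       tuple(-p[i])),
                        reverse=True)
        return p[scored]

    pop = sort_pop(pop)
    for _ in range(config.generations):
        new = [pop[i].copy() for i in range(config.elitism)]
        while len(new) < config.population:
            # binary tournament selection
            a, b = rng.integers(0, config.population, 2)
            p1 = pop[a] if fitness(pop[a]) >= fitness(pop[b]) else pop[b]
            a, b = rng.integers(0, config.population, 2)
            p2 = pop[a] if fitness(pop[a]) >= fitness(pop[b]) else pop[b]
            child = p1.copy()
            if rng.random() < config.crossover_rate:
                take = rng.random(nbits) < 0.5
                child[take] = p2[take]
            flip = rng.random(nbits) < config.mutation_rate
            child[flip] = 1 - child[flip]
            if child.sum() == 0:
                child[rng.integers(nbits)] = 1
            new.append(child)
        pop = sort_pop(np.array(new))

    feasible = {m: q for m, q in cache.items() if np.isfinite(q)}
    if not feasible:
        raise ValueError("no feasible feature subset")
    best_key = _parsimony_pick(
        {tuple(i for i, b in enumerate(m) if b): q
         for m, q in feasible.items()}, config.parsimony_tol)
    mask_idx = list(best_key)
    model = fit_mlr(X, y, mask=mask_idx, feature_names=names)
    model.q2 = loo_q2(X, y, mask=mask_idx, feature_names=names)
    return tuple(names[i] for i in mask_idx), model


# ---------------------------------------------------------------------------
# Fingerprint table I/O
# ---------------------------------------------------------------------------

def write_fingerprint_table(path, X: np.ndarray, y: np.ndarray,
                            sep: str = "\t") -> None:
    """Write a delimited fingerprint/affinity table (FP1..FP6 + logRBA).

    Integer bits are written exactly; FP6 with three decimals.
    """
    X = np.asarray(X, float)
    lines = [sep.join(list(FP_NAMES) + ["logRBA"])]
    for row, val in zip(X, y):
        fields = [str(int(v)) for v in row[:5]] + [f"{row[5]:.3f}",
                                                   f"{float(val):.4f}"]
        lines.append(sep.join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_fingerprint_table(path, sep: str = "\t"
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Read a fingerprint/affinity table written by
    :func:`write_fingerprint_table` (or transcribed externally)."""
    import pandas as pd

    df = pd.read_csv(path, sep=sep)
    missing = [c for c in list(FP_NAMES) + ["logRBA"] if c not in df.columns]
    if missing:
        raise ValueError(f"fingerprint table missing columns: {missing}")
    X = df[list(FP_NAMES)].to_numpy(float)
    y = df["logRBA"].to_numpy(float)
    return X, y
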