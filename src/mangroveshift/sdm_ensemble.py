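"""Ensemble habitat-suitability modelling with explicit threshold selection.

Six presence/absence model families — GLM (linear logistic), GAM (spline
logistic), CTA (single classification tree), FDA (discriminant analysis on
polynomial basis expansions), GBM (boosted shallow trees) and RF (random
forest) — are evaluated by repeated 70/30 split-sample cross-validation on
overall accuracy (ACC), the rank-based AUC, and the true skill statistic
(TSS = sensitivity + specificity - 1).  Families whose mean cross-validated
TSS exceeds 0.8 enter a weighted-average ensemble, weights proportional to
TSS.  Candidate probability thresholds are found by exhaustive scan under
six optimisation criteria; their mean, median and most-conservative (max)
summaries are compared on threshold-dependent statistics and the best
summary becomes the habitat-suitability threshold.

All learners sit behind one probabilistic-classifier contract (fit on a
covariate frame, return P(presence) in [0, 1]); the backends are sklearn
estimators but nothing downstream depends on that.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer
from sklearn.tree import DecisionTreeClassifier

from .domain import substream

FAMILIES = ("GLM", "GAM", "CTA", "FDA", "GBM", "RF")

DEFAULT_CRITERIA = ("maxTSS", "maxKappa", "sens=spec", "prevalence", "minROCdist", "fixed-0.5")

#: Minimum mean cross-validated TSS for ensemble membership.
DEFAULT_TSS_MIN = 0.8

_DEFAULT_HYPERPARAMS = {
    "GLM": {"max_iter": 2000},
    "GAM": {"n_knots": 5, "degree": 3, "C": 1000.0, "max_iter": 2000},
    "CTA": {"min_samples_leaf": 10},
    "FDA": {"degree": 2},
    "GBM": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
    "RF": {"n_estimators": 100, "min_samples_leaf": 5},
}


@dataclass(frozen=True)
class LearnerSpec:
    """One model family with frozen hyperparameters and a seed."""

    family: str
    hyperparams: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")

    def resolved_hyperparams(self) -> dict:
        hp = dict(_DEFAULT_HYPERPARAMS[self.family])
        hp.update(self.hyperparams)
        return hp


class FittedLearner:
    """Probabilistic classifier over a fixed predictor list."""

    def __init__(self, spec: LearnerSpec, predictors, estimator):
        self.spec = spec
        self.predictors = list(predictors)
        self.estimator = estimator
        self._pos_index = int(np.where(estimator.classes_ == 1)[0][0])

    def predict_prob(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.predictors].to_numpy(dtype=float)
        return self.estimator.predict_proba(X)[:, self._pos_index]


def _build_estimator(spec: LearnerSpec):
    hp = spec.resolved_hyperparams()
    fam, seed = spec.family, spec.seed
    if fam == "GLM":
        # C = inf: plain maximum-likelihood logistic regression
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=hp["max_iter"])
    if fam == "GAM":
        return Pipeline(
            [
                ("splines", SplineTransformer(n_knots=hp["n_knots"], degree=hp["degree"])),
                ("logit", LogisticRegression(C=hp["C"], solver="lbfgs", max_iter=hp["max_iter"])),
            ]
        )
    if fam == "CTA":
        return DecisionTreeClassifier(min_samples_leaf=hp["min_samples_leaf"], random_state=seed)
    if fam == "FDA":
        return Pipeline(
            [
                ("basis", PolynomialFeatures(degree=hp["degree"], include_bias=False)),
                ("lda", LinearDiscriminantAnalysis()),
            ]
        )
    if fam == "GBM":
        return GradientBoostingClassifier(
            n_estimators=hp["n_estimators"],
            max_depth=hp["max_depth"],
            learning_rate=hp["learning_rate"],
            random_state=seed,
        )
    if fam == "RF":
        return RandomForestClassifier(
            n_estimators=hp["n_estimators"],
            min_samples_leaf=hp["min_samples_leaf"],
            random_state=seed,
            n_jobs=1,
        )
    raise ValueError(fam)  # pragma: no cover - guarded by LearnerSpec


def fit_learner(spec: LearnerSpec, train: pd.DataFrame, predictors) -> FittedLearner:
    """Fit one family on the training records (post-screening predictors)."""
    y = train["habitat"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = train[list(predictors)].to_numpy(dtype=float)
    const = np.ptp(X, axis=0) == 0
    if const.any():
        bad = [p for p, c in zip(predictors, const) if c]
        raise ValueError(f"degenerate (constant) predictors: {bad}")
    est = _build_estimator(spec)
    est.fit(X, y)
    return FittedLearner(spec, predictors, est)


# --------------------------------------------------------------------------
# evaluation metrics
# --------------------------------------------------------------------------

def tss_from_rates(sensitivity: float, specificity: float) -> float:
    """TSS identity: sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def binary_auc_from_rates(sensitivity: float, specificity: float) -> float:
    """ROC area of a binary (already-thresholded) predictor."""
    return (sensitivity + specificity) / 2.0


def confusion_metrics(obs, prob, thr: float) -> dict:
    """Confusion table and threshold-dependent statistics at ``prob >= thr``."""
    if not 0.0 <= thr <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    obs = np.asarray(obs, dtype=int)
    prob = np.asarray(prob, dtype=float)
    if obs.shape != prob.shape:
        raise ValueError("obs and prob must have equal length")
    if len(np.unique(obs)) < 2:
        raise ValueError("observations must contain both classes")
    pred = prob >= thr
    tp = int(np.sum(pred & (obs == 1)))
    fp = int(np.sum(pred & (obs == 0)))
    tn = int(np.sum(~pred & (obs == 0)))
    fn = int(np.sum(~pred & (obs == 1)))
    n = len(obs)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (acc - pe) / (1.0 - pe) if pe < 1.0 else 0.0
    return {
        "TP": tp,
        "FP": fp,
        "TN": tn,
        "FN": fn,
        "sensitivity": sens,
        "specificity": spec,
        "ACC": acc,
        "kappa": kappa,
        "TSS": tss_from_rates(sens, spec),
    }


def rank_auc(obs, prob) -> float:
    """Mann-Whitney AUC; ties contribute 1/2.

    For a binary predictor this reduces to (sensitivity + specificity) / 2.
    """
    obs = np.asarray(obs, dtype=int)
    prob = np.asarray(prob, dtype=float)
    n1 = int(obs.sum())
    n0 = len(obs) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: observations contain a single class")
    ranks = stats.rankdata(prob)
    return float((ranks[obs == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def cv_split(table: pd.DataFrame, train_frac: float = 0.70, reps: int = 10, seed: int = 0):
    """Repeated random 70/30 partitions with both classes in every subset."""
    y = table["habitat"].to_numpy(dtype=int)
    if len(table) < 50:
        raise ValueError("need >= 50 records for cross-validation")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class table cannot be split")
    rng = substream(seed, "sdm.cv")
    n = len(table)
    n_train = int(np.floor(train_frac * n))
    splits = []
    for _ in range(reps):
        for _attempt in range(100):
            perm = rng.permutation(n)
            tr, va = perm[:n_train], perm[n_train:]
            if len(np.unique(y[tr])) == 2 and len(np.unique(y[va])) == 2:
                splits.append((tr, va))
                break
        else:  # pragma: no cover - pathological class imbalance
            raise RuntimeError("could not draw a split with both classes present")
    return splits


@dataclass
class CVResult:
    """Per-repetition evaluation of every family, plus validation probabilities."""

    report: pd.DataFrame            # family, rep, ACC, AUC, TSS, threshold
    splits: list                    # (train_idx, valid_idx) pairs
    valid_probs: dict               # family -> list of per-rep probability arrays

    def family_means(self) -> pd.DataFrame:
        return self.report.groupby("family")[["ACC", "AUC", "TSS"]].mean().reset_index()


def evaluate_families(
    table: pd.DataFrame,
    predictors,
    families=FAMILIES,
    train_frac: float = 0.70,
    reps: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated split-sample evaluation of each family.

    Per repetition, TSS is the maximum over the validation threshold scan
    (the customary reporting convention for this statistic) and ACC is
    taken at that same threshold; AUC is rank-based on the raw
    probabilities.
    """
    splits = cv_split(table, train_frac=train_frac, reps=reps, seed=seed)
    y = table["habitat"].to_numpy(dtype=int)
    rows, valid_probs = [], {f: [] for f in families}
    for fam in families:
        spec = LearnerSpec(fam, seed=seed)
        for rep, (tr, va) in enumerate(splits):
            fitted = fit_learner(spec, table.iloc[tr], predictors)
            prob = fitted.predict_prob(table.iloc[va])
            valid_probs[fam].append(prob)
            thr = optimal_thresholds(y[va], prob, criteria=("maxTSS",))["maxTSS"]
            m = confusion_metrics(y[va], prob, thr)
            rows.append(
                {
                    "family": fam,
                    "rep": rep,
                    "ACC": m["ACC"],
                    "AUC": rank_auc(y[va], prob),
                    "TSS": m["TSS"],
                    "threshold": thr,
                }
            )
    return CVResult(report=pd.DataFrame(rows), splits=splits, valid_probs=valid_probs)


# --------------------------------------------------------------------------
# ensemble
# --------------------------------------------------------------------------

@dataclass
class EnsembleMember:
    family: str
    learner: FittedLearner
    tss: float
    weight: float


@dataclass
class EnsembleModel:
    """TSS-weighted average of the retained family models."""

    members: list
    tss_min: float

    def __post_init__(self):
        w = np.array([m.weight for m in self.members])
        if not (np.all(w >= 0) and np.isclose(w.sum(), 1.0)):
            raise ValueError("weights must be non-negative and sum to 1")
        if any(m.tss <= self.tss_min for m in self.members):
            raise ValueError(f"every member must have TSS > {self.tss_min}")

    def predict_prob(self, table: pd.DataFrame) -> np.ndarray:
        return sum(m.weight * m.learner.predict_prob(table) for m in self.members)

    def member_probs(self, table: pd.DataFrame) -> dict:
        return {m.family: m.learner.predict_prob(table) for m in self.members}


def build_ensemble(fitted: dict, mean_tss: dict, tss_min: float = DEFAULT_TSS_MIN) -> EnsembleModel:
    """Retain families with mean CV TSS above the cutoff; weight by TSS.

    ``fitted`` maps family -> FittedLearner (refit on all records);
    ``mean_tss`` maps family -> mean cross-validated TSS.
    """
    kept = {f: t for f, t in mean_tss.items() if t > tss_min}
    if not kept:
        raise ValueError(
            f"no family exceeds the TSS cutoff {tss_min}; best was "
            f"{max(mean_tss, key=mean_tss.get)} at {max(mean_tss.values()):.3f}"
        )
    total = sum(kept.values())
    members = [
        EnsembleMember(family=f, learner=fitted[f], tss=t, weight=t / total)
        for f, t in kept.items()
    ]
    return EnsembleModel(members=members, tss_min=tss_min)


# --------------------------------------------------------------------------
# thresholds
# --------------------------------------------------------------------------

def _candidate_cutpoints(prob: np.ndarray) -> np.ndarray:
    uniq = np.unique(prob)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.unique(np.concatenate([uniq, mids]))


def optimal_thresholds(obs, prob, criteria=DEFAULT_CRITERIA) -> dict:
    """One threshold per optimisation criterion by exhaustive scan.

    The scan runs over the sorted unique predicted probabilities and their
    midpoints; ties break toward the lower threshold.
    """
    if not criteria:
        raise ValueError("empty criteria list")
    obs = np.asarray(obs, dtype=int)
    prob = np.asarray(prob, dtype=float)
    if len(np.unique(obs)) < 2:
        raise ValueError("threshold optimisation needs both classes")
    cuts = np.clip(_candidate_cutpoints(prob), 0.0, 1.0)

    # vectorized confusion across all cutpoints
    pred = prob[None, :] >= cuts[:, None]
    pos, neg = obs == 1, obs == 0
    tp = (pred & pos).sum(axis=1)
    fp = (pred & neg).sum(axis=1)
    fn = pos.sum() - tp
    tn = neg.sum() - fp
    n = len(obs)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    tss = sens + spec - 1.0
    acc = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = np.where(pe < 1.0, (acc - pe) / np.where(pe < 1.0, 1.0 - pe, 1.0), 0.0)
    prevalence_gap = np.abs(pred.mean(axis=1) - obs.mean())
    roc_dist = np.sqrt((1 - sens) ** 2 + (1 - spec) ** 2)

    out = {}
    for crit in criteria:
        if crit == "maxTSS":
            k = int(np.argmax(tss))
        elif crit == "maxKappa":
            k = int(np.argmax(kappa))
        elif crit == "sens=spec":
            k = int(np.argmin(np.abs(sens - spec)))
        elif crit == "prevalence":
            k = int(np.argmin(prevalence_gap))
        elif crit == "minROCdist":
            k = int(np.argmin(roc_dist))
        elif crit == "fixed-0.5":
            out[crit] = 0.5
            continue
        else:
            raise ValueError(f"unknown threshold criterion {crit!r}")
        out[crit] = float(cuts[k])  # argmin/argmax return the first (lowest) optimum
    return out


@dataclass
class ThresholdReport:
    """Mean/median/conservative threshold summaries with their statistics."""

    candidates: dict                # criterion -> threshold
    stats: pd.DataFrame             # rows mean/median/conservative
    selected: str                   # winning summary name
    selected_threshold: float


def select_suitability_threshold(candidates: dict, obs, prob) -> ThresholdReport:
    """Compare mean/median/most-conservative candidate summaries.

    Each summary is scored on how many of {sensitivity, TSS, kappa, AUC}
    it maximises across the three; ties go to the higher TSS, then the
    lower threshold.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    values = np.array(list(candidates.values()), dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 candidate thresholds to summarise")
    summaries = {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "conservative": float(values.max()),
    }
    rows = []
    for name, thr in summaries.items():
        m = confusion_metrics(obs, prob, min(max(thr, 0.0), 1.0))
        rows.append(
            {
                "summary": name,
                "threshold": thr,
                "sensitivity": m["sensitivity"],
                "specificity": m["specificity"],
                "TSS": m["TSS"],
                "kappa": m["kappa"],
                "ACC": m["ACC"],
                "AUC": binary_auc_from_rates(m["sensitivity"], m["specificity"]),
            }
        )
    table = pd.DataFrame(rows).set_index("summary")
    score = pd.Series(0, index=table.index, dtype=int)
    for stat in ("sensitivity", "TSS", "kappa", "AUC"):
        score[table[stat] == table[stat].max()] += 1
    ranked = sorted(
        table.index,
        key=lambda s: (-score[s], -table.loc[s, "TSS"], table.loc[s, "threshold"]),
    )
    best = ranked[0]
    return ThresholdReport(
        candidates=dict(candidates),
        stats=table.reset_index(),
        selected=best,
        selected_threshold=float(summaries[best]),
    )


# --------------------------------------------------------------------------
# suitability surfaces
# --------------------------------------------------------------------------

def suitability_summary(ensemble: EnsembleModel, scenario_tables: dict, thr: float, regions: dict | None = None) -> dict:
    """Per-scenario suitability of scored wetland points.

    ``scenario_tables`` maps a scenario name (e.g. ``present``,
    ``SSP5-8.5``) to a point table carrying that scenario's covariates.
    A point is suitable iff the ensemble probability >= ``thr``.  Returns,
    per scenario, the scored table, the northernmost suitable latitude
    (NaN when nothing is suitable) and percentage-suitable per named
    latitude region.
    """
    if not 0.0 <= thr <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = {}
    for scen, table in scenario_tables.items():
        if len(table) == 0:
            raise ValueError(f"scenario {scen!r} has an empty point set")
        prob = ensemble.predict_prob(table)
        suitable = prob >= thr
        scored = table[["id", "lon", "lat"]].copy()
        scored["probability"] = prob
        scored["suitable"] = suitable
        scored["scenario"] = scen
        northernmost = float(table["lat"].to_numpy()[suitable].max()) if suitable.any() else float("nan")
        fractions = {}
        for name, (lat0, lat1) in (regions or {}).items():
            sel = ((table["lat"] >= lat0) & (table["lat"] < lat1)).to_numpy()
            fractions[name] = 100.0 * suitable[sel].mean() if sel.any() else float("nan")
        out[scen] = {
            "scored": scored,
            "northernmost_suitable_lat": northernmost,
            "fraction_suitable_pct": fractions,
        }
    return out
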