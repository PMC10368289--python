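"""Generative inference: random-forest classification of diversity profiles.

The pipeline reformulates the neutrality question as supervised binary
classification.  Training data are simulated from the age-structured model
with parameters drawn from a prior:

    b ~ N(0, b_sd)  (with an explicit point mass of exact zeros),
    mu ~ U(1e-5, 1e-3),
    p_death ~ U(0.02, 0.1),
    c_thresh ~ discrete uniform on {1, ..., a_max} (a_max from a pilot
    stationary-age draw; the top draw maps to the unrestricted ALL pool).

Each simulated population is sampled at a fixed sample size, its diversity
profile (13 Hill numbers, q = 0..3 step 0.25) is the feature vector, and
the label records whether the generating process was unbiased (b = 0) or
biased (b != 0).  Separate forests are trained per sample size; prediction
is the majority vote of the T trees.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.model_selection import train_test_split

from .core import (ALL, ParameterError, SimParams, SteadyStateError, as_rng,
                   child_seed)
from .diversity import DEFAULT_Q_GRID, DiversityProfile, diversity_profile
from .simulate import run_to_steady_state, sample_variants

__all__ = ["PriorSpec", "draw_training_params", "build_training_set",
           "train_classifier", "classify", "classify_profiles",
           "permutation_importance", "ClassifierBundle",
           "LABEL_UNBIASED", "LABEL_BIASED"]

LABEL_UNBIASED = "unbiased"
LABEL_BIASED = "biased"

_FEATURES = [f"q{q:g}" for q in DEFAULT_Q_GRID]


@dataclass(frozen=True)
class PriorSpec:
    """Prior over simulator parameters for training-set generation.

    ``unbiased_fraction`` is the explicit point mass on b = 0 (a continuous
    normal prior alone would label no example unbiased); biased draws are
    resampled until |b| >= b_min so the two classes stay well defined.
    """

    b_sd: float = 1e-3
    mu_range: tuple = (1e-5, 1e-3)
    p_death_range: tuple = (0.02, 0.1)
    unbiased_fraction: float = 0.5
    b_min: float = 1e-6

    def __post_init__(self):
        if self.b_sd <= 0:
            raise ParameterError("b_sd must be positive")
        for name, (lo, hi) in (("mu_range", self.mu_range),
                               ("p_death_range", self.p_death_range)):
            if not (lo < hi):
                raise ParameterError(f"{name} must be a non-degenerate interval")
        if not (0.0 < self.unbiased_fraction < 1.0):
            raise ParameterError("unbiased_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return {"b_sd": self.b_sd, "mu_range": list(self.mu_range),
                "p_death_range": list(self.p_death_range),
                "unbiased_fraction": self.unbiased_fraction,
                "b_min": self.b_min}


def _pilot_a_max(N: int, p_death: float, rng) -> int:
    """Age of the oldest individual in one stationary-age pilot draw."""
    ages = rng.geometric(p_death, size=N) - 1
    return max(1, int(ages.max()))


def draw_training_params(prior: PriorSpec, rng, N: int = 100_000) -> tuple[SimParams, str]:
    """One prior draw: (SimParams, label)."""
    rng = as_rng(rng)
    p_death = float(rng.uniform(*prior.p_death_range))
    mu = float(rng.uniform(*prior.mu_range))
    a_max = _pilot_a_max(N, p_death, rng)
    c_draw = int(rng.integers(1, a_max + 1))
    c_thresh = ALL if c_draw >= a_max else c_draw
    if rng.random() < prior.unbiased_fraction:
        b = 0.0
        label = LABEL_UNBIASED
    else:
        b = float(rng.normal(0.0, prior.b_sd))
        while abs(b) < prior.b_min:
            b = float(rng.normal(0.0, prior.b_sd))
        label = LABEL_BIASED
    return SimParams(N=N, mu=mu, p_death=p_death, c_thresh=c_thresh, b=b), label


def build_training_set(prior: PriorSpec, n_examples: int, sample_size,
                       N: int = 100_000, rng=None,
                       q_grid=DEFAULT_Q_GRID,
                       max_skip_fraction: float = 0.05):
    """Simulate labeled diversity profiles.

    ``sample_size`` may be a single size (returns one DataFrame) or a
    sequence of sizes (returns ``{n: DataFrame}``); every size is sampled
    from the *same* simulated populations, so a multi-size training run
    costs one steady-state simulation per example.  Each DataFrame holds
    the 13 feature columns, the label, and the generating parameters.
    ``N`` scales the simulations (the study-scale default is 1e5; reduced
    N gives desk-scale training sets).  Examples whose simulation fails to
    reach steady state are skipped; more than ``max_skip_fraction`` skips
    is an error.
    """
    single = np.isscalar(sample_size)
    sizes = [int(sample_size)] if single else [int(s) for s in sample_size]
    if n_examples < 100:
        raise ParameterError("n_examples must be >= 100 for a usable training set")
    if max(sizes) > N:
        raise ParameterError(f"sample_size {max(sizes)} exceeds N={N}")
    rng = as_rng(rng)
    rows = {n: [] for n in sizes}
    done = 0
    skipped = 0
    max_skips = int(max_skip_fraction * n_examples) + 1
    while done < n_examples:
        params, label = draw_training_params(prior, rng, N=N)
        try:
            pop, _ = run_to_steady_state(params, rng)
        except SteadyStateError:
            skipped += 1
            if skipped > max_skips:
                raise RuntimeError(
                    f"more than {max_skip_fraction:.0%} of simulations failed "
                    "to reach steady state") from None
            continue
        for n in sizes:
            cfg = sample_variants(pop, n, rng)
            prof = diversity_profile(cfg, q_grid=q_grid)
            row = dict(zip(_FEATURES, prof.values))
            row.update(label=label, b=params.b, mu=params.mu,
                       p_death=params.p_death,
                       c_thresh=-1 if params.is_all_pool else int(params.c_thresh),
                       n=n)
            rows[n].append(row)
        done += 1
    if skipped:
        warnings.warn(f"{skipped} simulations skipped (no steady state)",
                      stacklevel=2)
    frames = {n: pd.DataFrame(r) for n, r in rows.items()}
    return frames[sizes[0]] if single else frames


@dataclass
class ClassifierBundle:
    """Per-sample-size random forests plus their training provenance."""

    forests: dict
    T: int
    prior: dict
    seed: int | None
    feature_names: list = field(default_factory=lambda: list(_FEATURES))
    heldout_accuracy: dict = field(default_factory=dict)
    heldout: dict = field(default_factory=dict)   # n -> (X, y) arrays
    sim_settings: dict = field(default_factory=dict)

    @property
    def sample_sizes(self) -> list[int]:
        return sorted(self.forests)

    def save(self, path) -> None:
        """Persist as a directory: model binary + metadata JSON."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        joblib.dump({"forests": self.forests, "heldout": self.heldout}, path / "model.joblib")
        meta = {"T": self.T, "prior": self.prior, "seed": self.seed,
                "feature_names": self.feature_names,
                "heldout_accuracy": {str(k): v for k, v in self.heldout_accuracy.items()},
                "sample_sizes": self.sample_sizes,
                "sim_settings": self.sim_settings}
        (path / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "ClassifierBundle":
        path = Path(path)
        blob = joblib.load(path / "model.joblib")
        meta = json.loads((path / "metadata.json").read_text())
        return cls(forests=blob["forests"], T=meta["T"], prior=meta["prior"],
                   seed=meta["seed"], feature_names=meta["feature_names"],
                   heldout_accuracy={int(k): v for k, v in meta["heldout_accuracy"].items()},
                   heldout=blob.get("heldout", {}),
                   sim_settings=meta.get("sim_settings", {}))


def _training_matrix(training: pd.DataFrame):
    X = training[_FEATURES].to_numpy(dtype=np.float64)
    y = (training["label"] == LABEL_BIASED).to_numpy(dtype=np.int64)
    return X, y


def train_classifier(training, T: int = 500, rng=None,
                     heldout_fraction: float = 0.2) -> ClassifierBundle:
    """Train per-sample-size random forests on labeled diversity profiles.

    ``training`` is a DataFrame (single sample size, column ``n``) or a
    mapping ``{sample_size: DataFrame}``.  Each forest uses bootstrap
    resampling and sqrt(13) random feature subsetting at splits; held-out
    accuracy is recorded from a stratified 20% split.
    """
    rng = as_rng(rng)
    if isinstance(training, pd.DataFrame):
        sizes = training["n"].unique()
        training = {int(s): training[training["n"] == s] for s in sizes}
    bundle = ClassifierBundle(forests={}, T=int(T), prior={}, seed=None)
    for n, df in sorted(training.items()):
        X, y = _training_matrix(df)
        if np.unique(y).size < 2:
            raise ParameterError(
                f"training set for n={n} contains a single class; "
                "both unbiased and biased examples are required")
        seed = child_seed(rng)
        X_tr, X_ho, y_tr, y_ho = train_test_split(
            X, y, test_size=heldout_fraction, stratify=y, random_state=seed)
        forest = RandomForestClassifier(
            n_estimators=int(T), max_features="sqrt", bootstrap=True,
            random_state=seed, n_jobs=1)
        forest.fit(X_tr, y_tr)
        bundle.forests[int(n)] = forest
        bundle.heldout[int(n)] = (X_ho, y_ho)
        bundle.heldout_accuracy[int(n)] = float(forest.score(X_ho, y_ho))
    return bundle


def _as_feature_matrix(profiles) -> tuple[np.ndarray, int]:
    if isinstance(profiles, DiversityProfile):
        profiles = [profiles]
    ns = {p.n for p in profiles}
    if len(ns) != 1:
        raise ParameterError("all profiles in a batch must share a sample size")
    X = np.vstack([p.as_array() for p in profiles])
    return X, ns.pop()


def classify_profiles(bundle: ClassifierBundle, profiles) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized classification; returns (labels, vote_fractions)."""
    X, n = _as_feature_matrix(profiles)
    if n not in bundle.forests:
        raise ParameterError(
            f"no forest trained for sample size n={n}; available: "
            f"{bundle.sample_sizes}")
    forest = bundle.forests[n]
    votes = np.zeros(X.shape[0])
    for tree in forest.estimators_:
        votes += tree.predict(X)
    votes /= len(forest.estimators_)
    labels = np.where(votes > 0.5, LABEL_BIASED, LABEL_UNBIASED)
    return labels, votes


def classify(bundle: ClassifierBundle, profile: DiversityProfile) -> tuple[str, float]:
    """Label one profile; returns (label, fraction of trees voting biased)."""
    labels, votes = classify_profiles(bundle, profile)
    return str(labels[0]), float(votes[0])


def permutation_importance(bundle: ClassifierBundle, heldout=None,
                           sample_size: int | None = None,
                           n_permutations: int = 20, rng=None) -> pd.DataFrame:
    """Per-feature permutation importance (mean accuracy drop on held-out
    data when one feature column is shuffled).

    ``heldout`` may be a DataFrame of labeled profiles or None (the
    bundle's stored held-out split is used).  Returns a DataFrame indexed
    by feature with columns (importance, std), one row set per sample size.
    """
    rng = as_rng(rng)
    sizes = [sample_size] if sample_size is not None else bundle.sample_sizes
    out = []
    for n in sizes:
        if n not in bundle.forests:
            raise ParameterError(f"no forest for n={n}; available: {bundle.sample_sizes}")
        if heldout is not None:
            df = heldout[heldout["n"] == n] if "n" in heldout.columns else heldout
            X, y = _training_matrix(df)
        else:
            X, y = bundle.heldout[n]
        if X.shape[0] == 0 or np.unique(y).size < 2:
            raise ParameterError("held-out set must be non-empty with both labels")
        res = _sk_permutation_importance(
            bundle.forests[n], X, y, scoring="accuracy",
            n_repeats=int(n_permutations), random_state=child_seed(rng), n_jobs=1)
        for i, name in enumerate(bundle.feature_names):
            out.append({"n": n, "feature": name, "q": float(name[1:]),
                        "importance": float(res.importances_mean[i]),
                        "std": float(res.importances_std[i])})
    return pd.DataFrame(out)
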