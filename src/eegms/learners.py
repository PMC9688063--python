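"""The classifier pool and its hyperparameter search space.

Nine learner families mirror the usual auto-ML pool for tabular
biomedical data: discriminant analysis, tree ensembles, random-feature
kernel classifiers, k-nearest neighbors, SVMs, regularized linear models,
naive Bayes, small neural networks, and decision trees. Each family owns a
bounded hyperparameter domain (log-scaled where natural); a configuration
is a ``(learner_name, params)`` pair that can be sampled, encoded as a
numeric vector for the surrogate model, and built into a fitted-ready
scikit-learn pipeline.
"""

from __future__ import annotations

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.kernel_approximation import RBFSampler
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["SearchSpace", "default_search_space", "LEARNER_NAMES"]

LEARNER_NAMES = (
    "discriminant", "ensemble", "kernel", "knn", "svm",
    "linear", "naive_bayes", "net", "tree",
)

# Parameter domain grammar: ("log", lo, hi) continuous log-uniform;
# ("int_log", lo, hi) integer log-uniform; ("float", lo, hi) uniform;
# ("choice", (options...)) categorical.
_DOMAINS: dict[str, dict[str, tuple]] = {
    "svm": {
        "kernel": ("choice", ("linear", "rbf", "poly2", "poly3")),
        "C": ("log", 1e-3, 1e3),
        "gamma": ("log", 1e-3, 1e3),
    },
    "knn": {"n_neighbors": ("int_log", 1, 50)},
    "tree": {"min_samples_leaf": ("int_log", 1, 64)},
    "ensemble": {
        "n_estimators": ("int_log", 50, 400),
        "min_samples_leaf": ("int_log", 1, 16),
    },
    "linear": {"C": ("log", 1e-3, 1e3)},
    "naive_bayes": {"var_smoothing": ("log", 1e-12, 1e-3)},
    "net": {
        "hidden": ("int_log", 4, 64),
        "alpha": ("log", 1e-6, 1e-1),
    },
    "discriminant": {
        "kind": ("choice", ("linear", "quadratic")),
        "shrinkage": ("float", 0.0, 1.0),
    },
    "kernel": {
        "gamma": ("log", 1e-3, 1e1),
        "C": ("log", 1e-3, 1e3),
    },
}


def _build(name: str, p: dict) -> Pipeline:
    if name == "svm":
        kernel = p["kernel"]
        # bounded iterations: pathological (C, gamma) corners must fail
        # fast with a bad objective value, not hang the optimizer
        kw = {"C": p["C"], "probability": False, "random_state": 0,
              "max_iter": 100_000}
        if kernel == "linear":
            est = SVC(kernel="linear", **kw)
        elif kernel == "rbf":
            est = SVC(kernel="rbf", gamma=p["gamma"], **kw)
        else:
            est = SVC(kernel="poly", degree=int(kernel[-1]), gamma=p["gamma"], **kw)
    elif name == "knn":
        est = KNeighborsClassifier(n_neighbors=int(p["n_neighbors"]))
    elif name == "tree":
        est = DecisionTreeClassifier(
            min_samples_leaf=int(p["min_samples_leaf"]), random_state=0
        )
    elif name == "ensemble":
        est = RandomForestClassifier(
            n_estimators=int(p["n_estimators"]),
            min_samples_leaf=int(p["min_samples_leaf"]),
            random_state=0, n_jobs=1,
        )
    elif name == "linear":
        est = LogisticRegression(C=p["C"], max_iter=2000)
    elif name == "naive_bayes":
        est = GaussianNB(var_smoothing=p["var_smoothing"])
    elif name == "net":
        est = MLPClassifier(
            hidden_layer_sizes=(int(p["hidden"]),), alpha=p["alpha"],
            max_iter=300, random_state=0,
        )
    elif name == "discriminant":
        if p["kind"] == "linear":
            est = LinearDiscriminantAnalysis(
                solver="lsqr", shrinkage=float(p["shrinkage"])
            )
        else:
            est = QuadraticDiscriminantAnalysis(reg_param=float(p["shrinkage"]))
    elif name == "kernel":
        est = make_pipeline(
            RBFSampler(gamma=p["gamma"], n_components=100, random_state=0),
            LogisticRegression(C=p["C"], max_iter=2000),
        )
    else:
        raise KeyError(f"unknown learner {name!r}")
    return make_pipeline(StandardScaler(), est)


class SearchSpace:
    """A pool of learners with bounded hyperparameter domains."""

    def __init__(self, domains: dict[str, dict[str, tuple]] | None = None):
        self.domains = dict(domains if domains is not None else _DOMAINS)
        for name, dom in self.domains.items():
            if not dom:
                raise ValueError(f"learner {name!r} has an empty domain")

    @property
    def learners(self) -> list[str]:
        return list(self.domains)

    def subset(self, names: list[str]) -> "SearchSpace":
        return SearchSpace({n: self.domains[n] for n in names})

    def sample(self, learner: str, rng: np.random.Generator) -> dict:
        """Draw one random configuration for ``learner``."""
        params = {}
        for key, spec in self.domains[learner].items():
            kind = spec[0]
            if kind == "log":
                params[key] = float(
                    10 ** rng.uniform(np.log10(spec[1]), np.log10(spec[2]))
                )
            elif kind == "int_log":
                v = 10 ** rng.uniform(np.log10(spec[1]), np.log10(spec[2] + 1))
                params[key] = int(np.clip(int(v), spec[1], spec[2]))
            elif kind == "float":
                params[key] = float(rng.uniform(spec[1], spec[2]))
            elif kind == "choice":
                params[key] = spec[1][rng.integers(len(spec[1]))]
            else:
                raise ValueError(f"unknown domain kind {kind!r}")
        return params

    def perturb(
        self, learner: str, params: dict, rng: np.random.Generator,
        scale: float = 0.1,
    ) -> dict:
        """A local neighbor of ``params`` (Gaussian in the encoded space,
        sd = ``scale`` x domain width; categoricals resampled w.p. 0.1)."""
        out = {}
        for key, spec in self.domains[learner].items():
            v, kind = params[key], spec[0]
            if kind == "log":
                width = np.log10(spec[2]) - np.log10(spec[1])
                lv = np.log10(v) + rng.normal(0, scale * width)
                out[key] = float(10 ** np.clip(lv, np.log10(spec[1]), np.log10(spec[2])))
            elif kind == "int_log":
                width = np.log10(spec[2] + 1) - np.log10(spec[1])
                lv = np.log10(v) + rng.normal(0, scale * width)
                out[key] = int(np.clip(round(10**lv), spec[1], spec[2]))
            elif kind == "float":
                out[key] = float(np.clip(
                    v + rng.normal(0, scale * (spec[2] - spec[1])),
                    spec[1], spec[2],
                ))
            else:
                out[key] = v if rng.random() < 0.9 else spec[1][rng.integers(len(spec[1]))]
        return out

    def to_vector(self, learner: str, params: dict) -> np.ndarray:
        """Numeric encoding of a configuration for the surrogate model."""
        vec = []
        for key, spec in self.domains[learner].items():
            v = params[key]
            kind = spec[0]
            if kind in ("log", "int_log"):
                vec.append(np.log10(float(v)))
            elif kind == "float":
                vec.append(float(v))
            else:
                vec.append(float(spec[1].index(v)))
        return np.array(vec)

    def build(self, learner: str, params: dict) -> Pipeline:
        """Instantiate an unfitted scikit-learn pipeline (with scaling)."""
        return _build(learner, params)


def default_search_space() -> SearchSpace:
    return SearchSpace()
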