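"""Phenotype derivation: Gaussian-mixture clustering, k selection, stability.

A Gaussian mixture (EM, best of ``n_init`` restarts) is the clustering family:
its likelihood makes AIC/BIC meaningful. Candidate k in 2..6 are compared by
mean silhouette width and BIC; because the two can disagree, the auditable
precedence rule is: among candidates whose silhouette is within 95% of the
maximum, the smallest BIC wins (the full per-k table is always returned).
Robustness is assessed by clusterwise bootstrap Jaccard stability
(Hennig-style maximum matching per reference cluster), and the three clusters
receive semantic labels from their centroid geometry: highest MESOR ->
Steady-High; of the rest, lowest amplitude -> Disrupted-Rhythmicity;
remainder -> Partial-Recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .config import DISRUPTED, PARTIAL_RECOVERY, STEADY_HIGH
from .errors import ConfigurationError

#: full covariance needs n >= k * d * (d + 3) / 2 observations, else diagonal
def _covariance_type(n: int, d: int, k: int) -> str:
    return "full" if n >= k * d * (d + 3) / 2 else "diag"


class PhenotypeModel:
    """Mixture-model clustering over a standardized feature matrix."""

    def __init__(self, matrix: pd.DataFrame):
        self.matrix = matrix
        self.X = matrix.to_numpy(dtype=float)

    def fit(
        self,
        k: int,
        seed: int = 0,
        n_init: int = 10,
        covariance_type: str | None = None,
    ) -> "PhenotypeResults":
        n, d = self.X.shape
        if k <= 1 or k >= n:
            raise ConfigurationError(f"k must satisfy 1 < k < n rows, got {k}")
        cov = covariance_type or _covariance_type(n, d, k)
        gm = GaussianMixture(
            n_components=k,
            covariance_type=cov,
            n_init=n_init,
            max_iter=500,
            tol=1e-6,
            reg_covar=1e-6,
            random_state=seed,
        ).fit(self.X)
        resp = gm.predict_proba(self.X)
        labels = np.argmax(resp, axis=1)
        loglik = float(gm.score(self.X) * n)
        if len(np.unique(labels)) > 1:
            sil = float(silhouette_score(self.X, labels))
        else:
            sil = -1.0
        return PhenotypeResults(
            model=self,
            k=k,
            assignments=labels,
            responsibilities=resp,
            means=gm.means_,
            covariance_type=cov,
            loglik=loglik,
            n_parameters=int(gm._n_parameters()),
            aic=float(gm.aic(self.X)),
            bic=float(gm.bic(self.X)),
            silhouette=sil,
            seed=seed,
            converged=bool(gm.converged_),
        )


@dataclass
class PhenotypeResults:
    """Fitted mixture: hard assignments, responsibilities and fit metrics."""

    model: PhenotypeModel
    k: int
    assignments: np.ndarray
    responsibilities: np.ndarray
    means: np.ndarray  # standardized-space centroids, (k, d)
    covariance_type: str
    loglik: float
    n_parameters: int
    aic: float
    bic: float
    silhouette: float
    seed: int
    converged: bool

    @property
    def patient_ids(self) -> np.ndarray:
        return self.model.matrix.index.to_numpy()

    def centroids(self, scaler=None) -> pd.DataFrame:
        """Cluster centroids, back-transformed to original units when a
        :class:`~circabp.features.Scaler` is given."""
        m = scaler.inverse_transform(self.means) if scaler is not None else self.means
        return pd.DataFrame(m, columns=self.model.matrix.columns)

    def summary(self) -> str:
        counts = np.bincount(self.assignments, minlength=self.k)
        lines = [
            f"Gaussian mixture, k={self.k} ({self.covariance_type} covariance)",
            f"  log-likelihood : {self.loglik:.2f}  (p={self.n_parameters})",
            f"  AIC {self.aic:.1f} | BIC {self.bic:.1f} | "
            f"silhouette {self.silhouette:.3f}",
            "  cluster sizes  : " + ", ".join(str(c) for c in counts),
        ]
        return "\n".join(lines)


def fit_mixture(
    matrix: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10,
    covariance_type: str | None = None,
) -> PhenotypeResults:
    return PhenotypeModel(matrix).fit(k, seed=seed, n_init=n_init,
                                      covariance_type=covariance_type)


def select_k(
    matrix: pd.DataFrame,
    k_range=range(2, 7),
    seed: int = 0,
    n_init: int = 10,
    silhouette_slack: float = 0.05,
) -> tuple[int, pd.DataFrame]:
    """Pick k: minimum BIC among candidates within 95% of the best silhouette.

    Returns the selected k and the full per-k metric table (loglik, AIC, BIC,
    silhouette, chosen flag) so the precedence rule is auditable.
    """
    ks = list(k_range)
    if not ks:
        raise ConfigurationError("empty k range")
    model = PhenotypeModel(matrix)
    if len(matrix) <= max(ks):
        raise ConfigurationError("need more rows than max(k_range)")
    fits = {k: model.fit(k, seed=seed, n_init=n_init) for k in ks}
    table = pd.DataFrame(
        {
            "k": ks,
            "loglik": [fits[k].loglik for k in ks],
            "aic": [fits[k].aic for k in ks],
            "bic": [fits[k].bic for k in ks],
            "silhouette": [fits[k].silhouette for k in ks],
        }
    )
    best_sil = table["silhouette"].max()
    thr = best_sil - silhouette_slack * abs(best_sil)
    candidates = table[table["silhouette"] >= thr]
    chosen = int(candidates.sort_values(["bic", "k"]).iloc[0]["k"])
    table["chosen"] = table["k"] == chosen
    return chosen, table


@dataclass
class StabilityReport:
    """Clusterwise bootstrap Jaccard stability of a reference clustering."""

    n_bootstrap: int
    n_used: int
    per_cluster_jaccard: np.ndarray
    overall_mean_jaccard: float
    per_resample: pd.DataFrame = field(repr=False, default=None)


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def bootstrap_stability(
    matrix: pd.DataFrame,
    reference: PhenotypeResults,
    n_bootstrap: int = 1000,
    seed: int = 0,
    n_init: int = 5,
) -> StabilityReport:
    """Refit on bootstrap resamples and match clusters by maximum Jaccard.

    For each resample the mixture is refitted at the reference k; each
    reference cluster is compared (over the unique patients present in the
    resample) with every resample cluster and takes its best Jaccard index.
    Resamples degenerating to fewer than k distinct rows are skipped and
    counted.
    """
    rng = np.random.default_rng(seed)
    n = len(matrix)
    k = reference.k
    ids = np.arange(n)
    ref_sets = [set(ids[reference.assignments == c]) for c in range(k)]
    rows = []
    jacc = []
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        uniq = np.unique(idx)
        sub = matrix.iloc[uniq]
        if len(np.unique(sub.to_numpy(), axis=0)) < k:
            rows.append({"resample": b, "skipped": True})
            continue
        res = PhenotypeModel(sub).fit(
            k, seed=int(rng.integers(0, 2**31 - 1)), n_init=n_init,
            covariance_type=reference.covariance_type,
        )
        boot_sets = [set(uniq[res.assignments == c]) for c in range(k)]
        per_cluster = []
        for c in range(k):
            ref_c = ref_sets[c] & set(uniq)
            per_cluster.append(max(_jaccard(ref_c, bs) for bs in boot_sets))
        jacc.append(per_cluster)
        rows.append({"resample": b, "skipped": False,
                     **{f"jaccard_{c}": per_cluster[c] for c in range(k)}})
    jacc = np.asarray(jacc, dtype=float)
    per_cluster_mean = jacc.mean(axis=0) if jacc.size else np.full(k, np.nan)
    return StabilityReport(
        n_bootstrap=n_bootstrap,
        n_used=int(jacc.shape[0]) if jacc.size else 0,
        per_cluster_jaccard=per_cluster_mean,
        overall_mean_jaccard=float(jacc.mean()) if jacc.size else float("nan"),
        per_resample=pd.DataFrame(rows),
    )


@dataclass
class PhenotypeLabeling:
    """Cluster index -> semantic phenotype label, with centroid evidence."""

    labels: dict[int, str]
    evidence: pd.DataFrame
    labeled: bool = True

    def apply(self, assignments: np.ndarray) -> np.ndarray:
        return np.asarray([self.labels[int(a)] for a in assignments], dtype=object)


def assign_labels(
    result: PhenotypeResults, scaler=None, n_cycles: int = 3
) -> PhenotypeLabeling:
    """Name the three clusters from centroid MESOR, amplitude and recovery.

    Steady-High = highest centroid MESOR; of the remaining two,
    Disrupted-Rhythmicity = lowest centroid amplitude (ties broken by recovery
    slope: the higher slope goes to Partial-Recovery). When k != 3 the labels
    are withheld and clusters keep numeric names.
    """
    cents = result.centroids(scaler)
    mesor_cols = [f"mesor_c{c}" for c in range(1, n_cycles + 1)]
    amp_cols = [f"amplitude_c{c}" for c in range(1, n_cycles + 1)]
    evidence = pd.DataFrame(
        {
            "cluster": range(result.k),
            "centroid_mesor": cents[mesor_cols].mean(axis=1),
            "centroid_amplitude": cents[amp_cols].mean(axis=1),
            "centroid_recovery_slope": cents.get(
                "recovery_slope", pd.Series(np.zeros(result.k))
            ),
            "size": np.bincount(result.assignments, minlength=result.k),
        }
    )
    if result.k != 3:
        return PhenotypeLabeling(
            labels={c: f"cluster_{c}" for c in range(result.k)},
            evidence=evidence,
            labeled=False,
        )
    order_mesor = evidence.sort_values("centroid_mesor", ascending=False)
    steady = int(order_mesor.iloc[0]["cluster"])
    rest = evidence[evidence["cluster"] != steady]
    if np.isclose(*rest["centroid_amplitude"].to_numpy()):
        # amplitude tie: the higher recovery slope is Partial-Recovery
        rest = rest.sort_values("centroid_recovery_slope", ascending=False)
        partial = int(rest.iloc[0]["cluster"])
        disrupted = int(rest.iloc[1]["cluster"])
    else:
        rest = rest.sort_values("centroid_amplitude")
        disrupted = int(rest.iloc[0]["cluster"])
        partial = int(rest.iloc[1]["cluster"])
    labels = {steady: STEADY_HIGH, disrupted: DISRUPTED, partial: PARTIAL_RECOVERY}
    evidence["label"] = evidence["cluster"].map(labels)
    return PhenotypeLabeling(labels=labels, evidence=evidence)
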