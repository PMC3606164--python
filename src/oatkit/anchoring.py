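"""Chromosome anchoring of linkage groups via aneuploid stocks.

Two complementary routes are implemented.  SNP deletion analysis: in an F1
of a monosomic maternal stock crossed to a euploid paternal line, loci on
the stock's missing chromosome carry only the paternal allele, so a
paternal-homozygous call where a heterozygote is expected (hemizygosity)
anchors the locus — and its linkage group — to that chromosome.  DArT
dose dilution: a marker on the missing chromosome hybridizes at half dose,
so its intensity falls in a lower cluster; fuzzy c-means separates full
from reduced dose and dose-affected markers vote for their group's
chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, check_random_state

from .formats import GenotypeMatrix, LinkageMap

UNASSIGNED = "UNASSIGNED"


@dataclass
class MonosomicStock:
    stock_id: str
    missing_chromosome: str
    background: str = ""
    paternal: str = ""


@dataclass
class AnchorReport:
    """Per-group hemizygous anchor counts and chromosome assignments."""

    counts: dict[str, dict[str, int]]  # group -> stock -> anchors
    assignments: dict[str, str]  # group -> chromosome or UNASSIGNED
    anomalies: dict[str, set] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, per_stock in sorted(self.counts.items()):
            for stock, n in sorted(per_stock.items()):
                rows.append({"group": group, "stock": stock, "anchors": n,
                             "assigned": self.assignments[group]})
        return pd.DataFrame(rows)


def _stock_chromosomes(stocks) -> dict[str, str]:
    if isinstance(stocks, dict):
        return dict(stocks)
    return {s.stock_id: s.missing_chromosome for s in stocks}


def detect_hemizygous(f1_calls: GenotypeMatrix, maternal_calls: pd.Series,
                      paternal_calls: pd.Series):
    """Per-stock hemizygous loci, plus maternal-only anomalies.

    Informative loci are those where the maternal background is homozygous
    A and the paternal parent is B.  At such loci an F1 call of B means the
    maternal copy is absent (hemizygous); H is the normal heterozygote; an
    A call is a candidate univalent shift / disomic reversion and is
    recorded as an anomaly, never used for anchoring; U is ignored.

    Returns ``(hemizygous, anomalies)``: two dicts stock -> set of loci.
    """
    loci = f1_calls.loci
    for parent, name in ((maternal_calls, "maternal"),
                         (paternal_calls, "paternal")):
        missing = set(loci) - set(parent.index)
        if missing:
            raise ValueError(f"{name} calls lack {len(missing)} F1 loci")
    informative = [m for m in loci
                   if maternal_calls[m] == "A" and paternal_calls[m] == "B"]
    hemi: dict[str, set] = {}
    anomalies: dict[str, set] = {}
    for stock in f1_calls.samples:
        row = f1_calls.calls.loc[stock]
        hemi[stock] = {m for m in informative if row[m] == "B"}
        anomalies[stock] = {m for m in informative if row[m] == "A"}
    return hemi, anomalies


def anchor_groups(hemizygous_sets: dict, lmap: LinkageMap, stocks,
                  min_anchors: int = 2,
                  anomalies: dict | None = None) -> AnchorReport:
    """Assign each linkage group to the chromosome of its best stock.

    For every group, hemizygous loci are counted per stock; the group is
    assigned to the missing chromosome of the stock with the strictly
    greatest count, provided that count reaches ``min_anchors``.  Ties and
    under-supported groups are left UNASSIGNED with the full count table
    in the report.
    """
    chrom_of = _stock_chromosomes(stocks)
    group_of = lmap.group_of()
    counts: dict[str, dict[str, int]] = {
        g: {s: 0 for s in sorted(chrom_of)} for g in lmap.groups
    }
    for stock, loci in hemizygous_sets.items():
        if stock not in chrom_of:
            continue
        for locus in loci:
            group = group_of.get(locus)
            if group is not None:
                counts[group][stock] += 1
    assignments: dict[str, str] = {}
    for group, per_stock in counts.items():
        ranked = sorted(per_stock.items(), key=lambda kv: (-kv[1], kv[0]))
        best_stock, best = ranked[0]
        runner_up = ranked[1][1] if len(ranked) > 1 else 0
        if best >= min_anchors and best > runner_up:
            assignments[group] = chrom_of[best_stock]
        else:
            assignments[group] = UNASSIGNED
    return AnchorReport(counts, assignments, anomalies or {})


# ---------------------------------------------------------------------------
# fuzzy c-means


class FuzzyKMeans(BaseEstimator, ClusterMixin):
    """Fuzzy c-means clustering (Bezdek), scikit-learn style.

    Memberships follow u_ij = 1 / sum_l (d_ij/d_lj)^(2/(m-1)) and centers
    are the membership^m-weighted means; the objective sum u^m d^2 is
    non-increasing per iteration.  The best of ``n_init`` random restarts
    is kept.  Points coincident with a center get crisp membership there.

    Parameters
    ----------
    n_clusters : number of clusters (2 for full- vs reduced-dose calling).
    m : fuzziness exponent, > 1.
    tol : convergence threshold on the objective decrease.
    max_iter, n_init, random_state : as in scikit-learn clusterers.

    Attributes
    ----------
    cluster_centers_ : (n_clusters, n_features) fitted centers.
    membership_ : (n_samples, n_clusters) membership matrix, rows sum to 1.
    objective_ : final objective value.
    n_iter_ : iterations of the winning restart.
    """

    def __init__(self, n_clusters: int = 2, m: float = 2.0, tol: float = 1e-6,
                 max_iter: int = 300, n_init: int = 5, random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    @staticmethod
    def _as_2d(values) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        return x

    def _memberships(self, x: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 0.0
        u = np.empty_like(d2)
        power = 1.0 / (self.m - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = (1.0 / d2) ** power
            u = inv / inv.sum(axis=1, keepdims=True)
        rows = zero.any(axis=1)
        u[rows] = 0.0
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        return u

    def fit(self, X, y=None):
        x = self._as_2d(X)
        if self.m <= 1.0:
            raise ValueError("fuzziness m must exceed 1")
        distinct = np.unique(x, axis=0)
        if len(distinct) < self.n_clusters:
            raise ValueError(
                f"need at least {self.n_clusters} distinct values, "
                f"got {len(distinct)}")
        rng = check_random_state(self.random_state)
        best = None
        for _ in range(self.n_init):
            centers = distinct[rng.choice(len(distinct), self.n_clusters,
                                          replace=False)].astype(float)
            prev = np.inf
            for it in range(1, self.max_iter + 1):
                u = self._memberships(x, centers)
                um = u ** self.m
                centers = (um.T @ x) / um.sum(axis=0)[:, None]
                d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
                obj = float((um * d2).sum())
                assert obj <= prev + 1e-9, "fuzzy c-means objective increased"
                if prev - obj < self.tol:
                    break
                prev = obj
            if best is None or obj < best[0]:
                best = (obj, centers, u, it)
        self.objective_, self.cluster_centers_, self.membership_, self.n_iter_ \
            = best
        self.labels_ = self.membership_.argmax(axis=1)
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        u = self._memberships(self._as_2d(X), self.cluster_centers_)
        return u.argmax(axis=1)

    def soft_predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        return self._memberships(self._as_2d(X), self.cluster_centers_)


def fuzzy_kmeans(values, k: int = 2, m: float = 2.0, tol: float = 1e-6,
                 max_iter: int = 300, restarts: int = 5, seed=None):
    """Functional wrapper over :class:`FuzzyKMeans`.

    Returns ``(centers, memberships)`` with centers sorted ascending (1-D
    input) and membership columns aligned to the sorted centers.
    """
    est = FuzzyKMeans(n_clusters=k, m=m, tol=tol, max_iter=max_iter,
                      n_init=restarts, random_state=seed).fit(values)
    centers = est.cluster_centers_
    u = est.membership_
    order = np.argsort(centers[:, 0], kind="stable")
    return centers[order], u[:, order]


# ---------------------------------------------------------------------------
# dose-dilution calling


@dataclass
class DoseCallReport:
    """Dose-affected sample sets per (background, representation)."""

    affected: dict  # (background, representation) -> set of samples
    skipped: list  # (background, representation, reason)

    def affected_by_representation(self) -> dict:
        out: dict[str, set] = {}
        for (_, rep), samples in self.affected.items():
            out.setdefault(rep, set()).update(samples)
        return out


def call_dose_affected(intensities: pd.DataFrame, background_groups,
                       variability_cv: float = 0.2,
                       center_ratio_max: float = 0.75,
                       membership_min: float = 0.8,
                       seed=0) -> DoseCallReport:
    """Find samples with diluted hybridization dose, per representation.

    Within each background, a representation is analyzed only when its
    intensity coefficient of variation reaches ``variability_cv`` (stable
    representations carry no dose signal).  Fuzzy c-means with k=2 splits
    the intensities; when the lower/upper center ratio is at most
    ``center_ratio_max`` — a real two-dose separation rather than noise —
    samples with membership >= ``membership_min`` in the lower cluster are
    called dose-affected.
    """
    groups = pd.Series(background_groups)
    report = DoseCallReport({}, [])
    for background in sorted(groups.unique()):
        samples = sorted(groups.index[groups == background])
        sub = intensities.loc[samples]
        for rep in intensities.columns:
            values = sub[rep].to_numpy(dtype=float)
            key = (background, rep)
            if len(values) < 2 or len(np.unique(values)) < 2:
                warnings.warn(
                    f"representation {rep!r} in background {background!r}: "
                    "too few samples for dose analysis", stacklevel=2)
                report.skipped.append((*key, "too_few_samples"))
                continue
            mean = values.mean()
            cv = values.std(ddof=1) / mean if mean else np.inf
            if cv < variability_cv:
                report.skipped.append((*key, "stable_intensity"))
                continue
            centers, u = fuzzy_kmeans(values, k=2, seed=seed)
            low, high = centers[0, 0], centers[1, 0]
            if high <= 0 or low / high > center_ratio_max:
                report.skipped.append((*key, "no_center_separation"))
                continue
            hit = {s for s, mem in zip(samples, u[:, 0])
                   if mem >= membership_min}
            report.affected[key] = hit
    return report


def dilution_anchor(dose_calls, stocks, marker_groups,
                    min_anchors: int = 2) -> AnchorReport:
    """Confirm group-to-chromosome assignments from dose-dilution calls.

    ``dose_calls`` maps representation (marker) -> set of dose-affected
    stocks; ``marker_groups`` maps marker -> linkage group.  A marker
    dose-affected in the stock missing chromosome X and linked to group G
    casts a vote G -> X; assignment follows the same strict-maximum /
    minimum-anchor rule as SNP deletion anchoring.
    """
    chrom_of = _stock_chromosomes(stocks)
    if isinstance(dose_calls, DoseCallReport):
        dose_calls = dose_calls.affected_by_representation()
    counts: dict[str, dict[str, int]] = {}
    for marker, affected in dose_calls.items():
        group = marker_groups.get(marker)
        if group is None:
            continue
        per = counts.setdefault(group, {s: 0 for s in sorted(chrom_of)})
        for stock in affected:
            if stock in per:
                per[stock] += 1
    assignments = {}
    for group, per_stock in counts.items():
        ranked = sorted(per_stock.items(), key=lambda kv: (-kv[1], kv[0]))
        best_stock, best = ranked[0]
        runner_up = ranked[1][1] if len(ranked) > 1 else 0
        if best >= min_anchors and best > runner_up:
            assignments[group] = chrom_of[best_stock]
        else:
            assignments[group] = UNASSIGNED
    return AnchorReport(counts, assignments)
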