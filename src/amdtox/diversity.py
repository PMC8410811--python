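"""Alpha-diversity estimation for OTU count tables.

Nonparametric richness estimators (bias-corrected Chao1 with its log-normal
95% interval, ACE, first-order jackknife), entropy-based diversity (Shannon
in nats with a seeded bootstrap interval, the Chao-Shen coverage-adjusted
Shannon, Simpson dominance and its inverse), Good's library coverage,
individual-based rarefaction via the exact hypergeometric expectation, and
Faith's phylogenetic diversity on a user-supplied newick tree.

All estimators consume a single sample's integer count vector (or its
frequency-count summary F_k = number of OTUs seen exactly k times); the
:class:`AlphaDiversity` estimator applies the battery column-wise to an
OTUs-by-samples table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .exceptions import EmptySampleError

__all__ = [
    "FrequencyCounts",
    "frequency_counts",
    "chao1",
    "ace",
    "jackknife1",
    "shannon",
    "np_shannon",
    "simpson",
    "goods_coverage",
    "rarefaction_curve",
    "faith_pd",
    "AlphaDiversity",
]


@dataclass(frozen=True)
class FrequencyCounts:
    """Abundance-frequency summary of one sample.

    ``f[k]`` is the number of OTUs observed exactly ``k`` times; ``s_obs``
    the observed richness; ``n`` the total read count.  Satisfies
    ``sum(k * f[k]) == n`` and ``sum(f.values()) == s_obs``.
    """

    f: dict[int, int]
    s_obs: int
    n: int

    def __getitem__(self, k: int) -> int:
        return self.f.get(k, 0)


def _counts_array(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("OTU counts must be integers")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("OTU counts must be >= 0")
    arr = arr[arr > 0]
    if arr.sum() == 0:
        raise EmptySampleError("sample contains no reads")
    return arr.astype(np.int64)


def frequency_counts(counts) -> FrequencyCounts:
    """Tabulate F_k, S_obs and N from one sample's count vector."""
    arr = _counts_array(counts)
    ks, reps = np.unique(arr, return_counts=True)
    return FrequencyCounts(
        f={int(k): int(r) for k, r in zip(ks, reps)},
        s_obs=int(arr.size),
        n=int(arr.sum()),
    )


# ---------------------------------------------------------------------------
# richness
# ---------------------------------------------------------------------------

def chao1(fc: FrequencyCounts, *, ci=True) -> dict[str, float]:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1)).

    The variance follows Chao's estimator-specific forms and the 95% bounds
    use the log-normal transformation of the estimated number of unseen
    OTUs, so the lower bound can never fall below S_obs.
    """
    f1, f2, s_obs = fc[1], fc[2], fc.s_obs
    est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    out = {"estimate": est}
    if not ci:
        return out
    if f1 > 0 and f2 > 0:
        var = (
            f1 * (f1 - 1) / (2.0 * (f2 + 1))
            + f1 * (2 * f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 2)
            + f1**2 * f2 * (2 * f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 4)
        )
    elif f1 > 0:
        var = (
            f1 * (f1 - 1) / 2.0
            + f1 * (2 * f1 - 1) ** 2 / 4.0
            - f1**4 / (4.0 * est)
        )
    else:
        var = 0.0
    t = est - s_obs
    if t > 0 and var > 0:
        k = math.exp(1.96 * math.sqrt(math.log(1.0 + var / t**2)))
        out["lci"], out["hci"] = s_obs + t / k, s_obs + t * k
    else:
        out["lci"] = out["hci"] = est
    return out


def ace(
    fc: FrequencyCounts,
    rare_threshold: int = 10,
    *,
    counts=None,
    ci=False,
    n_boot: int = 1000,
    random_state=None,
) -> dict[str, float]:
    """Abundance-based coverage estimator.

    S_ACE = S_abund + S_rare / C_ACE + (F1 / C_ACE) * gamma^2, where the
    sample coverage of the rare class is C_ACE = 1 - F1 / N_rare and
    gamma^2 is the standard coincidence estimate of the rare-class
    coefficient of variation (clamped at 0).  When every rare individual is
    a singleton (C_ACE = 0) the estimator is undefined and the function
    falls back to Chao1, recording ``fallback``.

    95% bounds, when requested, come from a seeded nonparametric bootstrap
    over the raw ``counts`` vector.
    """
    ks = np.array(sorted(fc.f), dtype=np.int64)
    reps = np.array([fc.f[int(k)] for k in ks], dtype=np.int64)
    rare = ks <= rare_threshold
    s_rare = int(reps[rare].sum())
    s_abund = int(reps[~rare].sum())
    n_rare = int((ks[rare] * reps[rare]).sum())
    f1 = fc[1]
    out: dict[str, float] = {}
    if s_rare == 0:
        out["estimate"] = float(fc.s_obs)
    elif n_rare == f1:  # all rare reads are singletons -> coverage 0
        out["estimate"] = chao1(fc, ci=False)["estimate"]
        out["fallback"] = "chao1"
    else:
        c_ace = 1.0 - f1 / n_rare
        sum_kk1 = float((ks[rare] * (ks[rare] - 1) * reps[rare]).sum())
        gamma2 = s_rare / c_ace * sum_kk1 / (n_rare * (n_rare - 1.0)) - 1.0
        gamma2 = max(gamma2, 0.0)
        out["estimate"] = s_abund + s_rare / c_ace + f1 / c_ace * gamma2
    if ci:
        if counts is None:
            raise ValueError("ACE bootstrap bounds need the raw count vector")
        arr = _counts_array(counts)
        rng = np.random.default_rng(random_state)
        p = arr / arr.sum()
        boots = np.empty(n_boot)
        for b in range(n_boot):
            resample = rng.multinomial(fc.n, p)
            boots[b] = ace(frequency_counts(resample), rare_threshold)["estimate"]
        out["lci"], out["hci"] = np.percentile(boots, [2.5, 97.5])
    return out


def jackknife1(fc: FrequencyCounts) -> float:
    """First-order abundance-based jackknife: S_obs + F1 (N-1)/N."""
    if fc.n <= 1:
        raise ValueError("jackknife1 requires more than one read")
    return fc.s_obs + fc[1] * (fc.n - 1) / fc.n


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def shannon(counts, *, ci=False, n_boot: int = 1000, random_state=None):
    """Plug-in Shannon entropy H = -sum p_i ln p_i, in nats.

    With ``ci=True`` returns a dict with seeded multinomial-bootstrap 95%
    percentile bounds.
    """
    arr = _counts_array(counts)
    p = arr / arr.sum()
    h = float(-np.sum(p * np.log(p)))
    if not ci:
        return h
    rng = np.random.default_rng(random_state)
    n = int(arr.sum())
    boots = np.empty(n_boot)
    for b in range(n_boot):
        q = rng.multinomial(n, p)
        q = q[q > 0] / n
        boots[b] = -np.sum(q * np.log(q))
    lci, hci = np.percentile(boots, [2.5, 97.5])
    return {"estimate": h, "lci": float(lci), "hci": float(hci)}


def np_shannon(counts) -> float:
    """Chao-Shen coverage-adjusted ("nonparametric") Shannon entropy.

    Relative abundances are shrunk by the Good coverage estimate
    (p~_i = C^ p_i with C^ = 1 - F1/N) and each term is inflated by its
    Horvitz-Thompson inclusion probability 1 - (1 - p~_i)^N.  Undefined
    (NaN) for an all-singleton sample, where C^ = 0.
    """
    arr = _counts_array(counts)
    n = arr.sum()
    fc = frequency_counts(arr)
    c_hat = 1.0 - fc[1] / n
    if c_hat == 0:
        return math.nan
    p_adj = c_hat * arr / n
    incl = 1.0 - (1.0 - p_adj) ** n
    return float(-np.sum(p_adj * np.log(p_adj) / incl))


def simpson(counts) -> tuple[float, float]:
    """Simpson dominance lambda = sum p_i^2 and its inverse 1/lambda."""
    arr = _counts_array(counts)
    p = arr / arr.sum()
    lam = float(np.sum(p**2))
    return lam, 1.0 / lam


def goods_coverage(fc: FrequencyCounts) -> float:
    """Good's library coverage as a percentage: (1 - F1/N) * 100."""
    return (1.0 - fc[1] / fc.n) * 100.0


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefaction_curve(counts, depths) -> np.ndarray:
    """Exact expected richness under subsampling without replacement.

    E[S_m] = sum_i 1 - C(N - N_i, m) / C(N, m), evaluated through log-gamma
    so that deep tables do not overflow.
    """
    arr = _counts_array(counts)
    n = int(arr.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if (depths < 0).any() or (depths > n).any():
        raise ValueError(f"rarefaction depths must lie in [0, N={n}]")
    out = np.empty(depths.shape, dtype=float)
    for j, m in enumerate(depths):
        keep = (n - arr) >= m  # otherwise C(N - N_i, m) = 0: OTU always seen
        log_ratio = (
            gammaln(n - arr[keep] + 1)
            - gammaln(n - arr[keep] - m + 1)
            + gammaln(n - m + 1)
            - gammaln(n + 1)
        )
        out[j] = (arr.size - keep.sum()) + np.sum(1.0 - np.exp(log_ratio))
    return out


# ---------------------------------------------------------------------------
# phylogenetic diversity
# ---------------------------------------------------------------------------

def faith_pd(observed_tips, tree) -> float:
    """Faith's PD: total branch length of the union of root-to-tip paths.

    ``tree`` is an ``skbio.TreeNode`` (see :func:`amdtox.io.read_tree`).
    Raises ``KeyError`` naming any observed tip absent from the tree.
    """
    tip_index = {t.name: t for t in tree.tips()}
    visited = set()
    total = 0.0
    for name in observed_tips:
        if name not in tip_index:
            raise KeyError(f"tip {name!r} not found in the tree")
        node = tip_index[name]
        while node.parent is not None:
            if id(node) in visited:
                break
            visited.add(id(node))
            if node.length is not None:
                if node.length < 0:
                    raise ValueError(f"negative branch length at {node.name!r}")
                total += node.length
            node = node.parent
    return total


# ---------------------------------------------------------------------------
# table-level estimator
# ---------------------------------------------------------------------------

class AlphaDiversity(BaseEstimator):
    """Column-wise alpha-diversity battery for an OTUs x samples table.

    Parameters
    ----------
    rare_threshold : int, default 10
        ACE rare/abundant split (reads).
    n_boot : int, default 1000
        Bootstrap resamples for the Shannon (and optional ACE) intervals.
    ace_ci : bool, default False
        Also bootstrap 95% bounds for ACE (slower).
    tree : skbio.TreeNode, optional
        When given, Faith's PD is computed over each sample's observed OTUs.
    random_state : int, optional
        Seed for every bootstrap.

    Attributes
    ----------
    report_ : pandas.DataFrame
        One row per sample: reads, S_obs, Chao1 (+95% bounds), ACE,
        jackknife, Shannon (+bootstrap bounds), NPShannon, Simpson
        (dominance and inverse), Good's coverage (%), optional Faith PD.
    """

    def __init__(self, rare_threshold: int = 10, n_boot: int = 1000,
                 ace_ci: bool = False, tree=None, random_state=None):
        self.rare_threshold = rare_threshold
        self.n_boot = n_boot
        self.ace_ci = ace_ci
        self.tree = tree
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        rows = []
        for sample in X.columns:
            counts = X[sample].to_numpy()
            fc = frequency_counts(counts)
            c1 = chao1(fc)
            a = ace(fc, self.rare_threshold, counts=counts, ci=self.ace_ci,
                    n_boot=self.n_boot, random_state=self.random_state)
            sh = shannon(counts, ci=True, n_boot=self.n_boot,
                         random_state=self.random_state)
            lam, inv = simpson(counts)
            row = {
                "sample_id": sample,
                "n_reads": fc.n,
                "s_obs": fc.s_obs,
                "chao1": c1["estimate"], "chao1_lci": c1["lci"], "chao1_hci": c1["hci"],
                "ace": a["estimate"],
                "ace_lci": a.get("lci", math.nan), "ace_hci": a.get("hci", math.nan),
                "jackknife1": jackknife1(fc),
                "shannon": sh["estimate"],
                "shannon_lci": sh["lci"], "shannon_hci": sh["hci"],
                "np_shannon": np_shannon(counts),
                "simpson_dominance": lam, "inv_simpson": inv,
                "goods_coverage_pct": goods_coverage(fc),
            }
            if self.tree is not None:
                observed = X.index[counts > 0]
                row["faith_pd"] = faith_pd(observed, self.tree)
            rows.append(row)
        self.report_ = pd.DataFrame(rows).set_index("sample_id")
        return self
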