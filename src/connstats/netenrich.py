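"""Network Level Analysis: enrichment of edgewise statistics in networks.

Instead of asking which single edges differ, NLA asks whether the edgewise
t-values concentrated in a network pair (or around a whole network) deviate
from the connectome-wide distribution:

* **Network pairs** (including within-network "pairs"): Welch's t comparing
  the pair's edge t-values against all connectome t-values.  Positive =
  enrichment (larger change than the connectome), negative = depletion.
* **Whole networks**: Welch's t on |t| over the edges incident to the
  network's parcels versus |t| over the connectome; only enrichment
  (one-sided) is interpreted.

Inference re-computes the same Welch statistics on every wild-bootstrap null
replicate of the edgewise t-vector and applies the Westfall-Young step-down
maxT procedure to control the family-wise error rate.  The pair family and
the whole-network family are corrected separately.

By default the connectome-wide reference group includes the pair's own edges
(the statistic's validity rests on the bootstrap null, not on two-sample
independence); a disjoint-complement reference is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .edges import edge_pairs
from .parcellation import NetworkAssignment

__all__ = [
    "merge_networks",
    "welch_t",
    "pair_enrichment",
    "whole_network_enrichment",
    "westfall_young_adjust",
    "run_nla",
    "NLAResult",
]


def merge_networks(
    assignment: NetworkAssignment, merge_spec: dict[str, str] | None = None
) -> NetworkAssignment:
    """Apply a raw-to-merged label mapping, returning a merged assignment.

    Small interdigitated networks are combined before inference so that
    enrichment is not biased toward large networks (e.g. the five motor
    networks into one SM label, salience + parietal memory into SAL/PMN,
    lateral + medial visual into VIS).  Every raw label must be mapped.
    """
    if merge_spec is None:
        merge_spec = assignment.merge_spec
    missing = set(np.unique(assignment.labels)) - set(merge_spec)
    if missing:
        raise ValueError(f"merge_spec leaves raw labels unmapped: {sorted(missing)}")
    merged = np.array([merge_spec[l] for l in assignment.labels], dtype=object)
    # identity spec over every *possible* merged label, not just those present
    ident = {l: l for l in set(merge_spec.values()) | set(merged)}
    return NetworkAssignment(labels=merged, merge_spec=ident)


def welch_t(values_a, values_b) -> float:
    """Welch's two-sample statistic ``(m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b)``."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / len(a) + vb / len(b))
    if denom == 0:
        raise ValueError("zero pooled variance; Welch statistic undefined")
    return float((a.mean() - b.mean()) / denom)


def _pair_labels(networks: np.ndarray, n_parcels: int):
    """Per-edge pair index and the list of unordered network pairs present."""
    ii, jj = edge_pairs(n_parcels)
    a = networks[ii]
    b = networks[jj]
    keys = [tuple(sorted((x, y))) for x, y in zip(a, b)]
    pairs = sorted(set(keys))
    lookup = {p: k for k, p in enumerate(pairs)}
    labels = np.array([lookup[k] for k in keys], dtype=np.int64)
    return labels, pairs


def _grouped_welch(
    T: np.ndarray, labels: np.ndarray, n_groups: int, reference: str
) -> np.ndarray:
    """Welch statistics of each label group vs the connectome, rows of T.

    ``T`` is (B, m); returns (B, n_groups).  Groups with < 2 edges (or a
    degenerate variance) come back NaN.
    """
    T = np.atleast_2d(T)
    # center rows: Welch numerator and variances are shift-invariant, and
    # all-equal inputs then give exact zeros instead of rounding residue
    T = T - T.mean(axis=1, keepdims=True)
    order = np.argsort(labels, kind="stable")
    starts = np.r_[0, np.flatnonzero(np.diff(labels[order])) + 1]
    present = labels[order][starts]
    Ts = T[:, order]
    s1 = np.add.reduceat(Ts, starts, axis=1)
    s2 = np.add.reduceat(Ts**2, starts, axis=1)
    counts = np.diff(np.r_[starts, T.shape[1]]).astype(float)

    n_tot = float(T.shape[1])
    tot1 = T.sum(axis=1, keepdims=True)
    tot2 = (T**2).sum(axis=1, keepdims=True)

    out = np.full((T.shape[0], n_groups), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        if reference == "overlap":
            ref_n = n_tot
            ref_mean = tot1 / n_tot
            ref_var = (tot2 - n_tot * ref_mean**2) / (n_tot - 1)
        elif reference == "complement":
            ref_n = n_tot - counts
            ref_mean = (tot1 - s1) / ref_n
            ref_var = (tot2 - s2 - ref_n * ref_mean**2) / (ref_n - 1)
        else:
            raise ValueError("reference must be 'overlap' or 'complement'")
        mean = s1 / counts
        var = (s2 - counts * mean**2) / (counts - 1)
        stat = (mean - ref_mean) / np.sqrt(var / counts + ref_var / ref_n)
        # exactly-zero mean difference is "no enrichment" even if degenerate
        stat = np.where(mean - ref_mean == 0, 0.0, stat)
        ok = counts >= 2
        stat[:, ~ok] = np.nan
        out[:, present] = stat
    return out


def pair_enrichment(
    t_edges: np.ndarray,
    networks: np.ndarray,
    reference: str = "overlap",
) -> pd.DataFrame:
    """Welch enrichment statistic for every unordered network pair.

    ``networks`` holds one (merged) label per parcel.  Pairs with fewer than
    2 edges get a NaN statistic and are excluded from any FWER family.
    """
    t = np.asarray(t_edges, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("edge t-values must be finite")
    n_parcels = len(networks)
    labels, pairs = _pair_labels(np.asarray(networks, dtype=object), n_parcels)
    stats = _grouped_welch(t[None, :], labels, len(pairs), reference)[0]
    counts = np.bincount(labels, minlength=len(pairs))
    return pd.DataFrame(
        {
            "network_a": [p[0] for p in pairs],
            "network_b": [p[1] for p in pairs],
            "n_edges": counts,
            "welch_t": stats,
        }
    )


def _incident_matrix(networks: np.ndarray, n_parcels: int, edge_set: str):
    """Boolean (K, m) indicator of each network's edge set."""
    ii, jj = edge_pairs(n_parcels)
    nets = sorted(set(networks))
    rows = []
    for net in nets:
        in_net_i = networks[ii] == net
        in_net_j = networks[jj] == net
        if edge_set == "incident":
            rows.append(in_net_i | in_net_j)
        elif edge_set == "within":
            rows.append(in_net_i & in_net_j)
        else:
            raise ValueError("edge_set must be 'incident' or 'within'")
    return nets, np.array(rows)


def _whole_network_welch(
    Tabs: np.ndarray, inc: np.ndarray, reference: str
) -> np.ndarray:
    """Welch of |t| over each network's edge set vs the connectome; (B, K)."""
    Tabs = np.atleast_2d(Tabs)
    Tabs = Tabs - Tabs.mean(axis=1, keepdims=True)  # shift-invariant, exact zeros
    counts = inc.sum(axis=1).astype(float)  # (K,)
    s1 = Tabs @ inc.T.astype(float)  # (B, K)
    s2 = (Tabs**2) @ inc.T.astype(float)
    n_tot = float(Tabs.shape[1])
    tot1 = Tabs.sum(axis=1, keepdims=True)
    tot2 = (Tabs**2).sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        if reference == "overlap":
            ref_n = n_tot
            ref_mean = tot1 / n_tot
            ref_var = (tot2 - n_tot * ref_mean**2) / (n_tot - 1)
        elif reference == "complement":
            ref_n = n_tot - counts
            ref_mean = (tot1 - s1) / ref_n
            ref_var = (tot2 - s2 - ref_n * ref_mean**2) / (ref_n - 1)
        else:
            raise ValueError("reference must be 'overlap' or 'complement'")
        mean = s1 / counts
        var = (s2 - counts * mean**2) / np.maximum(counts - 1, 1)
        stat = (mean - ref_mean) / np.sqrt(var / counts + ref_var / ref_n)
        stat = np.where(mean - ref_mean == 0, 0.0, stat)
        stat[:, counts < 2] = np.nan
        # a network covering the whole connectome compares the set with itself
        stat[:, counts == n_tot] = 0.0 if reference == "overlap" else np.nan
    return stat


def whole_network_enrichment(
    t_edges: np.ndarray,
    networks: np.ndarray,
    edge_set: str = "incident",
    reference: str = "overlap",
) -> pd.DataFrame:
    """Per-network Welch statistic on |t| over the network's edges vs the connectome.

    ``edge_set='incident'`` (default) takes every edge with at least one
    endpoint in the network; ``'within'`` restricts to edges with both.
    """
    t = np.asarray(t_edges, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("edge t-values must be finite")
    networks = np.asarray(networks, dtype=object)
    nets, inc = _incident_matrix(networks, len(networks), edge_set)
    stats = _whole_network_welch(np.abs(t)[None, :], inc, reference)[0]
    return pd.DataFrame(
        {"network": nets, "n_edges": inc.sum(axis=1), "welch_t": stats}
    )


def westfall_young_adjust(
    observed: np.ndarray,
    null_stats: np.ndarray,
    alternative: str = "two-sided",
) -> np.ndarray:
    """Westfall-Young step-down maxT adjusted p-values.

    Hypotheses are ordered by decreasing statistic (|observed| for the
    two-sided alternative), ties broken by index; for rank ``r`` the adjusted
    p is the fraction of replicates whose maximum null statistic over
    hypotheses ranked ``>= r`` reaches ``observed_r``, made monotone
    non-decreasing down the ordering.  NaN hypotheses are excluded from the
    family and come back NaN.
    """
    obs = np.asarray(observed, dtype=float)
    null = np.atleast_2d(np.asarray(null_stats, dtype=float))
    if null.shape[1] != obs.shape[0]:
        raise ValueError(
            f"null_stats columns ({null.shape[1]}) must align with "
            f"hypotheses ({obs.shape[0]})"
        )
    if alternative == "two-sided":
        obs_c = np.abs(obs)
        null_c = np.abs(null)
    elif alternative == "greater":
        obs_c = obs.copy()
        null_c = null.copy()
    else:
        raise ValueError("alternative must be 'two-sided' or 'greater'")

    keep = np.isfinite(obs_c)
    out = np.full(obs.shape, np.nan)
    if not keep.any():
        return out
    idx = np.flatnonzero(keep)
    obs_k = obs_c[idx]
    null_k = null_c[:, idx]
    null_k = np.where(np.isfinite(null_k), null_k, -np.inf)

    order = np.argsort(-obs_k, kind="stable")
    ordered_null = null_k[:, order]
    suffix_max = np.maximum.accumulate(ordered_null[:, ::-1], axis=1)[:, ::-1]
    q = (suffix_max >= obs_k[order][None, :]).mean(axis=0)
    q = np.maximum.accumulate(q)
    out[idx[order]] = q
    return out


def _raw_p(observed, null, alternative):
    obs = np.abs(observed) if alternative == "two-sided" else observed
    nul = np.abs(null) if alternative == "two-sided" else null
    nul = np.where(np.isfinite(nul), nul, -np.inf)
    with np.errstate(invalid="ignore"):
        p = (nul >= obs[None, :]).mean(axis=0)
    p = np.where(np.isfinite(obs), p, np.nan)
    return p


@dataclass
class NLAResult:
    """Pair-level and whole-network enrichment tables with FWER-adjusted p."""

    pairs: pd.DataFrame
    whole_networks: pd.DataFrame
    alpha: float
    B: int

    def significant_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["significant"]]


def run_nla(
    fit,
    assignment: NetworkAssignment | np.ndarray,
    alpha: float = 0.05,
    pair_reference: str = "overlap",
    whole_edge_set: str = "incident",
) -> NLAResult:
    """Full Network Level Analysis from a fitted edgewise model.

    ``fit`` is a fitted :class:`~connstats.edgefit.EdgewiseMarginalModel`
    (or a ``(t, null_t)`` tuple).  The bootstrap null t-vectors — which share
    their cluster sign draws across edges — are pushed through the same pair
    and whole-network Welch statistics to build the null families, then each
    family is Westfall-Young adjusted separately: pairs two-sided, whole
    networks one-sided (enrichment of |t|).
    """
    if isinstance(fit, tuple):
        t, null_t = fit
    else:
        t, null_t = fit.t_, getattr(fit, "null_t_", None)
    if null_t is None:
        raise ValueError("run_nla requires a bootstrap null (fit with B >= 1)")
    t = np.asarray(t, dtype=float)
    null_t = np.asarray(null_t, dtype=float)
    if isinstance(assignment, NetworkAssignment):
        networks = assignment.merged_labels
    else:
        networks = np.asarray(assignment, dtype=object)

    # pair family (two-sided)
    pairs = pair_enrichment(t, networks, reference=pair_reference)
    labels, pair_keys = _pair_labels(networks, len(networks))
    null_pair = _grouped_welch(null_t, labels, len(pair_keys), pair_reference)
    pairs["p_raw"] = _raw_p(
        pairs["welch_t"].to_numpy(), null_pair, alternative="two-sided"
    )
    pairs["p_fwer"] = westfall_young_adjust(
        pairs["welch_t"].to_numpy(), null_pair, alternative="two-sided"
    )
    pairs["significant"] = pairs["p_fwer"] < alpha

    # whole-network family (one-sided on |t|)
    whole = whole_network_enrichment(t, networks, edge_set=whole_edge_set,
                                     reference=pair_reference)
    nets, inc = _incident_matrix(networks, len(networks), whole_edge_set)
    null_whole = _whole_network_welch(np.abs(null_t), inc, pair_reference)
    whole["p_raw"] = _raw_p(
        whole["welch_t"].to_numpy(), null_whole, alternative="greater"
    )
    whole["p_fwer"] = westfall_young_adjust(
        whole["welch_t"].to_numpy(), null_whole, alternative="greater"
    )
    whole["significant"] = whole["p_fwer"] < alpha

    return NLAResult(pairs=pairs, whole_networks=whole, alpha=alpha,
                     B=null_t.shape[0])
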