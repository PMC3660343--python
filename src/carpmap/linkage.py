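"""Linkage-map construction for an outbred full-sib (CP) family.

The chain is the classical one: a locus genotype-frequency chi-square test
drops distorted markers; all retained pairs get a two-point maximum-likelihood
recombination fraction and LOD with linkage-phase inference; markers are
grouped by single linkage over (LOD, rf) thresholds; each group is ordered by
regression mapping (greedy insertion with a window-3 ripple, LOD-weighted
least squares on pairwise Kosambi distances); map distances are Kosambi cM.

Two-point likelihood model
--------------------------
Each parent transmits one of two haplotypes per locus pair; with parental
phase fixed, the gamete is parental with probability (1-r)/2 per arrangement
and recombinant with probability r/2.  The probability of each observable
joint genotype class (product of the two loci's code alphabets) is therefore
a polynomial of degree <= 2 in r, with coefficients fixed by the segregation
types and the two parents' phases.  The likelihood of the observed class
counts is maximized over r in [0, 0.5] for each of the <= 4 phase
combinations; the best phase wins, ties broken toward coupling.  LOD is
log10 L(r_hat) - log10 L(0.5).  A pair in which neither parent is
heterozygous at both loci carries no shared meioses (e.g. lmxll x nnxnp) and
is returned as rf = 0.5, LOD = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy import optimize, stats

from .dataio import (
    MISSING,
    PARENT_ALLELES,
    GenotypeTable,
    MarkerRecord,
    PipelineConfig,
    genotype_alphabet,
    offspring_code,
)

__all__ = [
    "TwoPointEstimate",
    "LinkageGroupMap",
    "GeneticMap",
    "kosambi_cM",
    "inverse_kosambi",
    "segregation_test",
    "estimate_rf",
    "two_point_matrix",
    "group_markers",
    "lod_sweep_group_counts",
    "order_group",
    "build_genetic_map",
    "map_stats",
]

# r values at which grid likelihoods are evaluated; the final estimate is
# refined by bounded scalar optimization so the grid only needs to bracket.
_R_GRID = np.linspace(1e-6, 0.5, 1001)


# ---------------------------------------------------------------------------
# mapping function
# ---------------------------------------------------------------------------


def kosambi_cM(r: float) -> float:
    """Kosambi map distance in centiMorgans: d = 25 ln((1+2r)/(1-2r))."""
    r = float(r)
    if r < 0 or r >= 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def inverse_kosambi(d_cM: float) -> float:
    """Recombination fraction for a Kosambi distance: r = tanh(d/50)/2."""
    d = float(d_cM)
    if d < 0:
        raise ValueError(f"map distance {d} must be >= 0")
    return 0.5 * np.tanh(d / 50.0)


# ---------------------------------------------------------------------------
# segregation distortion
# ---------------------------------------------------------------------------


def segregation_test(marker: MarkerRecord) -> tuple[float, int, float]:
    """Chi-square test of observed genotype-class counts against Mendelian
    expectation (1:1 for lmxll/nnxnp, 1:2:1 for hkxhk, 1:1:1:1 otherwise).

    Missing genotypes are excluded.  Returns (chi2, df, p).
    """
    alphabet = genotype_alphabet(marker.segregation_type)
    counts = np.array([sum(1 for c in marker.genotype_codes if c == a) for a in alphabet], float)
    n = counts.sum()
    if n == 0:
        raise ValueError(f"marker {marker.marker_id}: all genotypes missing")
    mother, father = PARENT_ALLELES[marker.segregation_type]
    expected_frac = np.zeros(len(alphabet))
    for m, f in itertools.product(mother, father):
        expected_frac[alphabet.index(offspring_code(m, f))] += 0.25
    expected = expected_frac * n
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = len(alphabet) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# two-point engine
# ---------------------------------------------------------------------------


@dataclass
class TwoPointEstimate:
    marker_a: str
    marker_b: str
    rf_hat: float
    lod: float
    n_informative: int
    phase_choice: str = "NA"


@lru_cache(maxsize=None)
def _pair_model(type_a: str, type_b: str) -> tuple[tuple[str, ...], np.ndarray, bool]:
    """Joint-class probability polynomials for a segregation-type pair.

    Returns (phase_labels, coeffs, informative) where ``coeffs`` has shape
    (n_phases, n_class_a * n_class_b, 3): quadratic coefficients [c0, c1, c2]
    of each joint class probability as a function of r.  Phase labels use
    'c' (coupling) / 'r' (repulsion) per parent, '.' for a parent whose phase
    is irrelevant (homozygous at either locus).
    """
    (ma, fa) = PARENT_ALLELES[type_a]
    (mb, fb) = PARENT_ALLELES[type_b]
    alpha_a = genotype_alphabet(type_a)
    alpha_b = genotype_alphabet(type_b)
    mother_het = ma[0] != ma[1] and mb[0] != mb[1]
    father_het = fa[0] != fa[1] and fb[0] != fb[1]
    phases_m = (0, 1) if mother_het else (0,)
    phases_f = (0, 1) if father_het else (0,)

    labels: list[str] = []
    all_coeffs: list[np.ndarray] = []
    for pm, pf in itertools.product(phases_m, phases_f):
        coeffs = np.zeros((len(alpha_a) * len(alpha_b), 3))
        for i, k, j, l in itertools.product(range(2), repeat=4):
            # mother gamete: locus-A allele ma[i], locus-B allele mb[k]
            pm_poly = (0.5, -0.5) if (k == i ^ pm) else (0.0, 0.5)
            pf_poly = (0.5, -0.5) if (l == j ^ pf) else (0.0, 0.5)
            ca = alpha_a.index(offspring_code(ma[i], fa[j]))
            cb = alpha_b.index(offspring_code(mb[k], fb[l]))
            row = ca * len(alpha_b) + cb
            coeffs[row, 0] += pm_poly[0] * pf_poly[0]
            coeffs[row, 1] += pm_poly[0] * pf_poly[1] + pm_poly[1] * pf_poly[0]
            coeffs[row, 2] += pm_poly[1] * pf_poly[1]
        lab_m = ("c" if pm == 0 else "r") if mother_het else "."
        lab_f = ("c" if pf == 0 else "r") if father_het else "."
        labels.append(lab_m + lab_f)
        all_coeffs.append(coeffs)
    return tuple(labels), np.stack(all_coeffs), (mother_het or father_het)


def _class_logprob(coeffs: np.ndarray, r: np.ndarray) -> np.ndarray:
    """log class probabilities, shape (..., n_class, len(r))."""
    r = np.atleast_1d(np.asarray(r, float))
    p = coeffs[..., 0:1] + coeffs[..., 1:2] * r + coeffs[..., 2:3] * r**2
    return np.log(np.maximum(p, 1e-300))


def _joint_counts(a: MarkerRecord, b: MarkerRecord) -> np.ndarray:
    alpha_a = genotype_alphabet(a.segregation_type)
    alpha_b = genotype_alphabet(b.segregation_type)
    ia = np.array([alpha_a.index(c) if c != MISSING else -1 for c in a.genotype_codes])
    ib = np.array([alpha_b.index(c) if c != MISSING else -1 for c in b.genotype_codes])
    ok = (ia >= 0) & (ib >= 0)
    return np.bincount(ia[ok] * len(alpha_b) + ib[ok], minlength=len(alpha_a) * len(alpha_b))


def _phase_restriction(a: MarkerRecord, b: MarkerRecord, labels: tuple[str, ...]) -> list[int]:
    """Indices of phase models consistent with any known marker phases."""
    want_m = want_f = None
    if a.phase[0] in "01" and b.phase[0] in "01":
        want_m = "c" if a.phase[0] == b.phase[0] else "r"
    if a.phase[1] in "01" and b.phase[1] in "01":
        want_f = "c" if a.phase[1] == b.phase[1] else "r"
    keep = []
    for idx, lab in enumerate(labels):
        if want_m is not None and lab[0] in "cr" and lab[0] != want_m:
            continue
        if want_f is not None and lab[1] in "cr" and lab[1] != want_f:
            continue
        keep.append(idx)
    return keep


def estimate_rf(a: MarkerRecord, b: MarkerRecord) -> TwoPointEstimate:
    """Two-point ML recombination fraction and LOD for one marker pair."""
    labels, coeffs, informative = _pair_model(a.segregation_type, b.segregation_type)
    counts = _joint_counts(a, b)
    n_shared = int(counts.sum())
    if not informative or n_shared == 0:
        return TwoPointEstimate(a.marker_id, b.marker_id, 0.5, 0.0, 0)

    keep = _phase_restriction(a, b, labels)
    best = (-np.inf, 0.5, "NA")
    for idx in keep:
        ll = counts @ _class_logprob(coeffs[idx], _R_GRID)
        g = int(np.argmax(ll))
        lo = _R_GRID[max(g - 1, 0)]
        hi = _R_GRID[min(g + 1, len(_R_GRID) - 1)]

        def negll(r: float, idx: int = idx) -> float:
            return -float(counts @ _class_logprob(coeffs[idx], np.array([r]))[:, 0])

        res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-9})
        cand = (-res.fun, float(np.clip(res.x, 0.0, 0.5)), labels[idx])
        if cand[0] > best[0] + 1e-9:
            best = cand
    ll_hat, rf_hat, phase = best
    ll_null = float(counts @ _class_logprob(coeffs[0], np.array([0.5]))[:, 0])
    lod = max(0.0, (ll_hat - ll_null) / np.log(10.0))
    if rf_hat > 0.5 - 1e-6:
        rf_hat, lod = 0.5, 0.0
    return TwoPointEstimate(a.marker_id, b.marker_id, rf_hat, lod, n_shared, phase)


def two_point_matrix(markers: list[MarkerRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All pairwise two-point estimates, vectorized over pairs.

    Returns symmetric (rf, lod, n_informative) matrices.  Uses the same
    likelihood as :func:`estimate_rf`, maximized on a fine grid with
    parabolic refinement (adequate for grouping and ordering; the scalar
    path refines further for single-pair queries).
    """
    n = len(markers)
    rf = np.full((n, n), 0.5)
    lod = np.zeros((n, n))
    ninf = np.zeros((n, n), int)
    np.fill_diagonal(rf, 0.0)

    # pre-encode genotype codes as alphabet indices (-1 missing)
    enc: list[np.ndarray] = []
    for m in markers:
        alpha = genotype_alphabet(m.segregation_type)
        enc.append(np.array([alpha.index(c) if c != MISSING else -1 for c in m.genotype_codes]))

    by_type: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            key = (markers[i].segregation_type, markers[j].segregation_type)
            by_type.setdefault(key, []).append((i, j))

    log10 = np.log(10.0)
    for (ta, tb), pairs in by_type.items():
        labels, coeffs, informative = _pair_model(ta, tb)
        nb = len(genotype_alphabet(tb))
        ncls = coeffs.shape[1]
        counts = np.zeros((len(pairs), ncls))
        for row, (i, j) in enumerate(pairs):
            ia, ib = enc[i], enc[j]
            ok = (ia >= 0) & (ib >= 0)
            counts[row] = np.bincount(ia[ok] * nb + ib[ok], minlength=ncls)
        shared = counts.sum(axis=1).astype(int)
        if not informative:
            for row, (i, j) in enumerate(pairs):
                ninf[i, j] = ninf[j, i] = 0
            continue
        # log-likelihood per pair per grid point, maximized over phases
        logp = _class_logprob(coeffs, _R_GRID)  # (n_phase, ncls, G)
        ll = np.einsum("pc,fcg->pfg", counts, logp)  # (pairs, phases, G)
        ll_best = ll.max(axis=1)  # (pairs, G)
        g = np.argmax(ll_best, axis=1)
        # parabolic refinement on the grid
        g_in = np.clip(g, 1, len(_R_GRID) - 2)
        y0 = ll_best[np.arange(len(pairs)), g_in - 1]
        y1 = ll_best[np.arange(len(pairs)), g_in]
        y2 = ll_best[np.arange(len(pairs)), g_in + 1]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        step = _R_GRID[1] - _R_GRID[0]
        r_hat = np.clip(_R_GRID[g_in] + shift * step, 0.0, 0.5)
        r_hat = np.where(g == 0, _R_GRID[0], r_hat)
        r_hat = np.where(g == len(_R_GRID) - 1, 0.5, r_hat)
        # evaluate exact log-likelihood at refined r_hat (max over phases)
        p = (
            coeffs[:, None, :, 0]
            + coeffs[:, None, :, 1] * r_hat[None, :, None]
            + coeffs[:, None, :, 2] * (r_hat**2)[None, :, None]
        )  # (phases, pairs, ncls)
        lp = np.log(np.maximum(p, 1e-300))
        ll_hat = np.einsum("pc,fpc->pf", counts, lp).max(axis=1)
        ll_null = ll[:, 0, -1]  # r ~ 0.5, phase-independent
        lods = np.maximum(0.0, (ll_hat - ll_null) / log10)
        near_null = r_hat > 0.5 - 1e-4
        r_hat = np.where(near_null, 0.5, r_hat)
        lods = np.where(near_null, 0.0, lods)
        for row, (i, j) in enumerate(pairs):
            if shared[row] == 0:
                continue
            rf[i, j] = rf[j, i] = r_hat[row]
            lod[i, j] = lod[j, i] = lods[row]
            ninf[i, j] = ninf[j, i] = shared[row]
    return rf, lod, ninf


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


def _linkage_graph(lod: np.ndarray, rf: np.ndarray, lod_threshold: float, max_rf: float) -> nx.Graph:
    n = lod.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu((lod >= lod_threshold) & (rf <= max_rf), k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


def group_markers(
    rf: np.ndarray, lod: np.ndarray, cfg: PipelineConfig
) -> list[list[int]]:
    """Single-linkage components over edges with LOD >= threshold and
    rf <= max_rf.  Groups sorted by size (desc), then smallest member index;
    singletons are returned too (callers treat them as unlinked)."""
    g = _linkage_graph(lod, rf, cfg.lod_group_threshold, cfg.max_rf)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def lod_sweep_group_counts(
    rf: np.ndarray, lod: np.ndarray, cfg: PipelineConfig
) -> dict[float, int]:
    """Diagnostic: number of non-singleton groups at each LOD of the sweep."""
    out: dict[float, int] = {}
    for threshold in cfg.lod_sweep:
        g = _linkage_graph(lod, rf, threshold, cfg.max_rf)
        out[threshold] = sum(1 for c in nx.connected_components(g) if len(c) > 1)
    return out


# ---------------------------------------------------------------------------
# ordering (regression mapping)
# ---------------------------------------------------------------------------


def _wls_positions(order: list[int], D: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, float]:
    """LOD-weighted least-squares positions along a fixed order.

    Minimizes sum w_ij (x_j - x_i - d_ij)^2 over pairs with finite distance
    and positive weight, with the first marker fixed at 0.  Returns positions
    in order-space and the weighted residual (the ordering objective).
    """
    n = len(order)
    rows_a: list[int] = []
    rows_b: list[int] = []
    ds: list[float] = []
    ws: list[float] = []
    for p in range(n):
        for q in range(p + 1, n):
            i, j = order[p], order[q]
            w = W[i, j]
            d = D[i, j]
            if w > 0 and np.isfinite(d):
                rows_a.append(p)
                rows_b.append(q)
                ds.append(d)
                ws.append(w)
    if not ds:
        return np.zeros(n), 0.0
    m = len(ds)
    A = np.zeros((m, n - 1))
    for r_, (p, q) in enumerate(zip(rows_a, rows_b)):
        if q > 0:
            A[r_, q - 1] += 1.0
        if p > 0:
            A[r_, p - 1] -= 1.0
    sw = np.sqrt(np.asarray(ws))
    x, *_ = np.linalg.lstsq(A * sw[:, None], np.asarray(ds) * sw, rcond=None)
    fitted = np.concatenate(([0.0], x))
    resid = A @ x - np.asarray(ds)
    return fitted, float((np.asarray(ws) * resid**2).sum())


def _ripple(order: list[int], D: np.ndarray, W: np.ndarray) -> tuple[list[int], float]:
    """One left-to-right pass permuting every window of 3 consecutive markers."""
    best_order = list(order)
    _, best_sse = _wls_positions(best_order, D, W)
    for w in range(len(best_order) - 2):
        window = best_order[w : w + 3]
        for perm in itertools.permutations(window):
            if list(perm) == best_order[w : w + 3]:
                continue
            cand = best_order[:w] + list(perm) + best_order[w + 3 :]
            _, sse = _wls_positions(cand, D, W)
            if sse < best_sse - 1e-12:
                best_order, best_sse = cand, sse
    return best_order, best_sse


def _reinsertion_pass(
    order: list[int], D: np.ndarray, W: np.ndarray, sse: float
) -> tuple[list[int], float]:
    """Try moving each marker to every other slot; keep improvements."""
    best_order, best_sse = list(order), sse
    for k in range(len(order)):
        base = best_order[:k] + best_order[k + 1 :]
        for slot in range(len(base) + 1):
            if slot == k:
                continue
            cand = base[:slot] + [best_order[k]] + base[slot:]
            _, s = _wls_positions(cand, D, W)
            if s < best_sse - 1e-12:
                best_order, best_sse = cand, s
    return best_order, best_sse


def order_group(
    members: list[int], rf: np.ndarray, lod: np.ndarray, ninf: np.ndarray | None = None
) -> tuple[list[int], list[float]]:
    """Order one linkage group and fit cM positions (regression mapping).

    Markers are inserted in decreasing-information order (sum of pair LODs);
    each insertion point minimizes the LOD-weighted SSE between fitted map
    distances and pairwise Kosambi distances, followed by a window-3 ripple.
    rf values above the grouping ceiling still contribute distances here.
    Returns (ordered member indices, nondecreasing positions starting at 0).
    """
    if len(members) == 1:
        return list(members), [0.0]
    sub = np.ix_(members, members)
    with np.errstate(divide="ignore"):
        ratio = (1.0 + 2.0 * rf[sub]) / np.maximum(1.0 - 2.0 * rf[sub], 1e-12)
    D = 25.0 * np.log(ratio)
    D[rf[sub] >= 0.5 - 1e-9] = np.inf
    W = lod[sub] ** 2  # LOD-squared weighting downplays weak, long distances
    np.fill_diagonal(W, 0.0)
    if len(members) == 2:
        d = D[0, 1] if np.isfinite(D[0, 1]) else 0.0
        return list(members), [0.0, float(d)]

    info = W.sum(axis=1)
    addition = sorted(range(len(members)), key=lambda k: (-info[k], k))
    order = addition[:2]
    for nxt in addition[2:]:
        best_order, best_sse = None, np.inf
        for slot in range(len(order) + 1):
            cand = order[:slot] + [nxt] + order[slot:]
            _, sse = _wls_positions(cand, D, W)
            if sse < best_sse:
                best_order, best_sse = cand, sse
        order, _ = _ripple(best_order, D, W)

    # polish: alternate ripple and single-marker reinsertion to a fixed point
    _, sse = _wls_positions(order, D, W)
    for _ in range(10):
        order, new_sse = _ripple(order, D, W)
        order, new_sse = _reinsertion_pass(order, D, W, new_sse)
        if new_sse >= sse - 1e-9:
            break
        sse = new_sse

    positions, _ = _wls_positions(order, D, W)
    # present markers sorted by fitted position, anchored at 0
    srt = np.argsort(positions, kind="stable")
    order = [order[k] for k in srt]
    pos = positions[srt]
    pos = pos - pos[0]
    pos = np.maximum.accumulate(pos)  # guard against numerically tiny inversions
    return [members[k] for k in order], [float(p) for p in pos]


# ---------------------------------------------------------------------------
# map assembly and statistics
# ---------------------------------------------------------------------------


@dataclass
class LinkageGroupMap:
    lg_id: str
    marker_ids: list[str]
    positions_cM: list[float]

    def __post_init__(self) -> None:
        if len(self.marker_ids) != len(self.positions_cM):
            raise ValueError("marker/position length mismatch")
        if self.positions_cM and abs(self.positions_cM[0]) > 1e-9:
            raise ValueError("first marker must sit at 0 cM")
        if any(b < a - 1e-9 for a, b in zip(self.positions_cM, self.positions_cM[1:])):
            raise ValueError("positions must be nondecreasing")

    @property
    def length_cM(self) -> float:
        return self.positions_cM[-1] if self.positions_cM else 0.0


@dataclass
class GeneticMap:
    groups: list[LinkageGroupMap]
    excluded: dict[str, str] = field(default_factory=dict)  # marker_id -> reason

    def position_of(self, marker_id: str) -> tuple[str, float] | None:
        for g in self.groups:
            if marker_id in g.marker_ids:
                return g.lg_id, g.positions_cM[g.marker_ids.index(marker_id)]
        return None

    def marker_to_lg(self) -> dict[str, tuple[str, float]]:
        out: dict[str, tuple[str, float]] = {}
        for g in self.groups:
            for mid, pos in zip(g.marker_ids, g.positions_cM):
                out[mid] = (g.lg_id, pos)
        return out


def build_genetic_map(table: GenotypeTable, cfg: PipelineConfig) -> tuple[GeneticMap, dict]:
    """Full linkage pipeline: distortion filter, two-point, group, order.

    Returns the map plus a diagnostics dict (lod sweep group counts, the
    rf/lod matrices and the retained marker list).
    """
    excluded: dict[str, str] = {}
    retained: list[MarkerRecord] = []
    for m in table.markers:
        chi2, df, p = segregation_test(m)
        if p < cfg.distortion_alpha:
            excluded[m.marker_id] = "distorted"
        else:
            retained.append(m)

    rf, lod, ninf = two_point_matrix(retained)
    groups = group_markers(rf, lod, cfg)
    sweep = lod_sweep_group_counts(rf, lod, cfg)

    lg_maps: list[LinkageGroupMap] = []
    lg_no = 0
    for comp in groups:
        if len(comp) == 1:
            excluded[retained[comp[0]].marker_id] = "unlinked"
            continue
        lg_no += 1
        order, positions = order_group(comp, rf, lod, ninf)
        lg_maps.append(
            LinkageGroupMap(
                f"LG{lg_no}",
                [retained[k].marker_id for k in order],
                positions,
            )
        )
    gmap = GeneticMap(lg_maps, excluded)
    diag = {
        "lod_sweep": sweep,
        "rf": rf,
        "lod": lod,
        "n_informative": ninf,
        "retained_ids": [m.marker_id for m in retained],
    }
    return gmap, diag


def map_stats(gmap: GeneticMap) -> "pd.DataFrame":
    """Per-LG table: n_markers, length_cM, avg/max adjacent spacing; a Total
    row sums markers and lengths (mean LG length = total length / n LGs)."""
    import pandas as pd

    rows = []
    for g in gmap.groups:
        gaps = np.diff(g.positions_cM) if len(g.positions_cM) > 1 else np.array([])
        rows.append(
            {
                "lg_id": g.lg_id,
                "n_markers": len(g.marker_ids),
                "length_cM": round(g.length_cM, 3),
                "avg_spacing_cM": round(g.length_cM / (len(g.marker_ids) - 1), 3)
                if len(g.marker_ids) > 1
                else np.nan,
                "max_spacing_cM": round(float(gaps.max()), 3) if gaps.size else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    total = {
        "lg_id": "Total",
        "n_markers": int(df["n_markers"].sum()) if len(df) else 0,
        "length_cM": round(float(df["length_cM"].sum()), 3) if len(df) else 0.0,
        "avg_spacing_cM": np.nan,
        "max_spacing_cM": np.nan,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
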