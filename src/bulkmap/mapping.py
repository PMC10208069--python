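"""Segregation testing, regional linkage and recombinant fine mapping.

Marker order is taken from physical position; only adjacent-pair
recombination fractions are estimated (EM for codominant F2 data, with
the double-heterozygote ambiguity handled in the E-step) and converted to
map distance with the Haldane (default) or Kosambi inverse. Fine mapping
intersects, over recombinant and non-recombinant individuals, the marker
intervals where a causal position is consistent with each individual's
phenotype under a dominant model (yellow phenotype <=> BB at the causal
locus; H counts as green-consistent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenomicInterval, GenotypeMatrix
from .errors import ConflictError

__all__ = [
    "chisq_segregation", "recombination_fractions", "find_recombinants",
    "delimit_interval", "panel_concordance", "RecombinantCall",
    "FineMapResult",
]


def chisq_segregation(n_dominant: int, n_recessive: int, ratio=(3, 1)):
    """Pearson goodness-of-fit of observed class counts against a ratio.

    One degree of freedom, no continuity correction; returns ``(chi2, p)``
    with the upper-tail p from chi2(1).
    """
    if n_dominant < 0 or n_recessive < 0:
        raise ValueError("counts must be >= 0")
    n = n_dominant + n_recessive
    if n == 0:
        raise ValueError("need at least one observation")
    total_ratio = ratio[0] + ratio[1]
    expected = [n * ratio[0] / total_ratio, n * ratio[1] / total_ratio]
    chi2, p = stats.chisquare([n_dominant, n_recessive], f_exp=expected)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# Two-point linkage
# ---------------------------------------------------------------------------

_CODE_TO_COUNT = {"A": 0, "H": 1, "B": 2}

# Definite recombinant-gamete counts per two-locus genotype class
# (B-allele counts at the two loci), coupling-phase F2. The double
# heterozygote (1,1) is ambiguous: 0 or 2 recombinant gametes.
_DEFINITE_RECOMB = {
    (0, 0): 0, (0, 1): 1, (0, 2): 2,
    (1, 0): 1, (1, 2): 1,
    (2, 0): 2, (2, 1): 1, (2, 2): 0,
}


def _em_recombination(counts: dict, n: int, tol: float = 1e-10,
                      max_iter: int = 200) -> float:
    """EM estimate of r from two-locus genotype class counts (coupling)."""
    definite = sum(_DEFINITE_RECOMB[c] * k for c, k in counts.items()
                   if c != (1, 1))
    n_hh = counts.get((1, 1), 0)
    r = 0.25
    for _ in range(max_iter):
        denom = (1 - r) ** 2 + r ** 2
        expected_hh = 0.0 if denom == 0 else n_hh * 2 * r ** 2 / denom
        r_new = (definite + expected_hh) / (2 * n)
        if abs(r_new - r) < tol:
            return r_new
        r = r_new
    return r


def haldane_cm(r: float) -> float:
    """Haldane inverse map function, d = -50 ln(1 - 2r)."""
    if r >= 0.5:
        return float("inf")
    return -50.0 * np.log(1 - 2 * r)


def kosambi_cm(r: float) -> float:
    """Kosambi inverse map function, d = 25 ln((1+2r)/(1-2r))."""
    if r >= 0.5:
        return float("inf")
    return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))


def recombination_fractions(matrix: GenotypeMatrix,
                            map_function: str = "haldane") -> pd.DataFrame:
    """Adjacent-pair recombination fractions and map distances.

    Returns a frame with one row per adjacent marker pair: the EM estimate
    of r over informative (non-missing at both markers) individuals, the
    map distance in cM, and the informative count. Pairs estimated at
    r >= 0.5 get infinite cM, a warning, and are excluded from the
    ``map_length_cm`` attribute stored on the frame.
    """
    if matrix.n_markers < 2:
        raise ValueError("need >= 2 markers")
    to_cm = {"haldane": haldane_cm, "kosambi": kosambi_cm}[map_function]
    rows = []
    for j in range(matrix.n_markers - 1):
        left = matrix.codes[:, j]
        right = matrix.codes[:, j + 1]
        ok = (left != "-") & (right != "-")
        counts: dict = {}
        for a, b in zip(left[ok], right[ok]):
            cls = (_CODE_TO_COUNT[a], _CODE_TO_COUNT[b])
            counts[cls] = counts.get(cls, 0) + 1
        n_inf = int(ok.sum())
        r = _em_recombination(counts, n_inf) if n_inf else np.nan
        cm = to_cm(r) if n_inf else np.nan
        if np.isfinite(r) and r >= 0.5:
            warnings.warn(
                f"markers {matrix.markers[j]}–{matrix.markers[j + 1]}: "
                f"r = {r:.3f} >= 0.5, distance undefined", stacklevel=2)
        rows.append((matrix.markers[j], matrix.markers[j + 1], r, cm, n_inf))
    df = pd.DataFrame(rows, columns=["left", "right", "r", "cM", "n_informative"])
    finite = df["cM"][np.isfinite(df["cM"])]
    df.attrs["map_length_cm"] = float(finite.sum())
    df.attrs["map_function"] = map_function
    return df


# ---------------------------------------------------------------------------
# Recombinant identification
# ---------------------------------------------------------------------------

@dataclass
class RecombinantCall:
    """An individual whose codes differ between two flanking markers."""

    individual: str
    breakpoints: list   # (left_marker, right_marker) pairs localizing crossovers
    phenotype: str | None


def find_recombinants(matrix: GenotypeMatrix, left_marker: str,
                      right_marker: str) -> list:
    """Individuals whose codes at the two markers differ (missing excluded).

    Breakpoints are localized by scanning all intervening markers: each
    adjacent informative pair with a code change contributes one
    breakpoint interval.
    """
    jl = matrix.marker_index(left_marker)
    jr = matrix.marker_index(right_marker)
    if jl > jr:
        jl, jr = jr, jl
    calls = []
    for i, ind in enumerate(matrix.ids):
        codes = matrix.codes[i, jl:jr + 1]
        informative = [(k, c) for k, c in enumerate(codes) if c != "-"]
        if len(informative) < 2:
            continue
        if informative[0][1] == informative[-1][1]:
            continue
        breakpoints = []
        for (k1, c1), (k2, c2) in zip(informative, informative[1:]):
            if c1 != c2:
                breakpoints.append((matrix.markers[jl + k1],
                                    matrix.markers[jl + k2]))
        calls.append(RecombinantCall(
            individual=ind, breakpoints=breakpoints,
            phenotype=matrix.phenotypes.get(ind)))
    return calls


# ---------------------------------------------------------------------------
# Interval delimitation
# ---------------------------------------------------------------------------

def _consistent_slots(codes: np.ndarray, phenotype: str) -> np.ndarray:
    """Per-slot consistency of a causal position with one individual.

    Slots alternate marker/gap over K markers (2K-1 slots): slot 2j is
    marker j, slot 2j+1 the gap between markers j and j+1. A position
    inherits the nearest flanking non-missing codes; where those flanks
    disagree (a crossover interval) the genotype is ambiguous and cannot
    exclude the position. Dominant model: yellow requires code B; green is
    consistent with A or H.
    """
    k = len(codes)
    slots = np.ones(2 * k - 1, dtype=bool)
    non_missing = [j for j in range(k) if codes[j] != "-"]

    def determinate(left_j, right_j):
        """Code of a position flanked by markers left_j..right_j, or None."""
        left = [j for j in non_missing if j <= left_j]
        right = [j for j in non_missing if j >= right_j]
        lcode = codes[left[-1]] if left else None
        rcode = codes[right[0]] if right else None
        if lcode is None or rcode is None:
            return lcode or rcode
        return lcode if lcode == rcode else None

    for s in range(2 * k - 1):
        j = s // 2
        code = (codes[j] if s % 2 == 0 and codes[j] != "-"
                else determinate(j, j + (0 if s % 2 == 0 else 1)))
        if code is None:
            continue  # ambiguous or unanchored: no exclusion
        if phenotype == "yellow" and code in ("A", "H"):
            slots[s] = False
        elif phenotype == "green" and code == "B":
            slots[s] = False
    return slots


@dataclass
class FineMapResult:
    """Outcome of recombinant-based delimitation."""

    interval: GenomicInterval
    left_marker: str
    right_marker: str
    n_recombinants: int
    n_individuals_used: int

    @property
    def width_bp(self) -> int:
        return self.interval.width_bp


def delimit_interval(recombinants, matrix: GenotypeMatrix,
                     model: str = "dominant") -> FineMapResult:
    """Intersect phenotype-consistent regions over scored individuals.

    Uses the recombinants plus every phenotyped individual in ``matrix``
    (non-recombinants also constrain the interval). The returned interval
    is bounded by the nearest markers flanking the consistent region; an
    empty intersection raises :class:`ConflictError` naming the individual
    at which the intersection first emptied.
    """
    if model != "dominant":
        raise ValueError(f"unsupported inheritance model {model!r}")
    if matrix.positions is None:
        raise ValueError("matrix must carry marker positions")
    k = matrix.n_markers
    consistent = np.ones(2 * k - 1, dtype=bool)
    recomb_ids = {rc.individual for rc in recombinants}
    missing_ph = [rc.individual for rc in recombinants
                  if rc.phenotype is None]
    if missing_ph:
        raise ValueError(f"recombinants without phenotype: {missing_ph}")
    n_used = 0
    conflicted = []
    for i, ind in enumerate(matrix.ids):
        phenotype = matrix.phenotypes.get(ind)
        if phenotype is None:
            continue
        n_used += 1
        new = consistent & _consistent_slots(matrix.codes[i], phenotype)
        if not new.any():
            conflicted.append(ind)
            continue
        consistent = new
    if conflicted:
        raise ConflictError(
            "no causal position consistent with all individuals; "
            f"conflicting: {conflicted}", individuals=conflicted)
    idx = np.flatnonzero(consistent)
    first, last = int(idx[0]), int(idx[-1])
    if not recombinants:
        warnings.warn("no recombinants supplied; interval is the full "
                      "flanking span", stacklevel=2)
    # nearest marker at/left of the region start and at/right of the end;
    # a region starting in gap (j, j+1) is bounded left by marker j
    left_j = first // 2 if first % 2 == 1 else max(first // 2 - 1, 0)
    # region starting AT marker j is flanked by marker j-1 (or j at the edge)
    if first % 2 == 0 and first // 2 == 0:
        left_j = 0
    right_j = ((last + 1) // 2 if last % 2 == 1
               else min(last // 2 + 1, k - 1))
    if last % 2 == 0 and last // 2 == k - 1:
        right_j = k - 1
    interval = GenomicInterval(matrix.chrom or "?",
                               int(matrix.positions[left_j]),
                               int(matrix.positions[right_j]))
    return FineMapResult(
        interval=interval, left_marker=matrix.markers[left_j],
        right_marker=matrix.markers[right_j],
        n_recombinants=len(recomb_ids), n_individuals_used=n_used)


# ---------------------------------------------------------------------------
# Diagnostic panel
# ---------------------------------------------------------------------------

def panel_concordance(panel: pd.DataFrame):
    """Phenotype/genotype agreement under the rule insertion <=> yellow.

    ``panel`` has columns id, phenotype ('green'/'yellow'), insertion
    (bool). Returns ``(n_concordant, n_total, perfect, fisher_p)`` with a
    two-sided Fisher exact p on the 2x2 phenotype x insertion table;
    degenerate margins give p = 1 with a warning.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    yellow = panel["phenotype"] == "yellow"
    ins = panel["insertion"].astype(bool)
    concordant = int(((yellow & ins) | (~yellow & ~ins)).sum())
    n_total = len(panel)
    table = np.array([
        [int((yellow & ins).sum()), int((yellow & ~ins).sum())],
        [int((~yellow & ins).sum()), int((~yellow & ~ins).sum())],
    ])
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        warnings.warn("degenerate 2x2 margin; Fisher p reported as 1",
                      stacklevel=2)
        fisher_p = 1.0
    else:
        fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return concordant, n_total, concordant == n_total, fisher_p
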