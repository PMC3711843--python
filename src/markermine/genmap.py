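"""Two-point linkage utilities for validating markers on RIL genotypes.

A recombinant inbred line (RIL) population is produced by selfing an F1 for
several generations; at F7 individuals are nearly homozygous (residual
heterozygosity (1/2)^6 ≈ 1.6%).  Repeated rounds of meiosis inflate the
observed recombinant fraction between the parental genotype classes: for a
selfed RIL at F∞ the expectation is R = 2r / (1 + 2r), where r is the
per-meiosis recombination fraction.  When the generation is known, r is
recovered by inverting the exact finite-generation two-locus selfing
recursion (the F∞ closed form r = R/(2(1−R)) is the fallback), which
removes the small downward bias the F∞ formula has at F7.
Map distances use the Kosambi function
d = 25 · ln((1 + 2r)/(1 − 2r)) cM, and linkage groups are the connected
components of the marker graph with edges at LOD above a threshold
(default 6.0).  Segregation distortion is screened with a 1-df chi-square
test against the expected 1:1 ratio of the two parental classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import MappingError

CALLS = ("A", "B", "H", "-")


@dataclass
class GenotypeMatrix:
    """Marker × individual genotype calls for an inbred population."""

    marker_ids: list
    individual_ids: list
    calls: np.ndarray            # shape (n_markers, n_individuals), dtype '<U1'
    generation: int = 7

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.marker_ids), len(self.individual_ids)):
            raise MappingError(
                f"genotype matrix shape {self.calls.shape} does not match "
                f"{len(self.marker_ids)} markers x "
                f"{len(self.individual_ids)} individuals"
            )
        if self.generation < 2:
            raise MappingError("generation must be >= 2 (F2 or later)")
        if len(self.individual_ids) < 2:
            raise MappingError("need at least 2 individuals")
        bad = ~np.isin(self.calls, CALLS)
        if bad.any():
            raise MappingError(f"invalid genotype call {self.calls[bad][0]!r}")

    def column(self, marker_id) -> np.ndarray:
        return self.calls[self.marker_ids.index(marker_id)]

    def heterozygote_fraction(self) -> float:
        called = np.isin(self.calls, ("A", "B", "H"))
        return float(np.count_nonzero(self.calls == "H") / called.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=self.marker_ids, columns=self.individual_ids
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, generation: int = 7):
        return cls(list(df.index), list(df.columns), df.to_numpy(), generation)


@dataclass
class DistortionResult:
    marker_id: str
    n_a: int
    n_b: int
    chi2: float
    p_value: float
    distorted: bool
    low_power: bool


def test_segregation_distortion(
    calls: Sequence[str] | np.ndarray,
    marker_id: str = "",
    alpha: float = 0.01,
    n_tests: int = 1,
) -> DistortionResult:
    """Chi-square (1 df) test of the observed A:B counts against 1:1.

    Heterozygous and missing calls are excluded.  ``n_tests`` applies a
    Bonferroni correction to ``alpha`` when screening many markers.  With
    fewer than 20 informative calls the result is flagged low-power rather
    than raising.
    """
    arr = np.asarray(calls, dtype="<U1")
    n_a = int(np.count_nonzero(arr == "A"))
    n_b = int(np.count_nonzero(arr == "B"))
    n = n_a + n_b
    if n == 0:
        return DistortionResult(marker_id, 0, 0, 0.0, 1.0, False, True)
    chi2 = (n_a - n_b) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return DistortionResult(
        marker_id, n_a, n_b, float(chi2), p,
        distorted=p < alpha / max(1, n_tests),
        low_power=n < 20,
    )


@dataclass
class TwoPointResult:
    marker_a: str
    marker_b: str
    n_informative: int
    r_hat: float               # observed recombinant fraction, in [0, 0.5]
    r_meiotic: float           # RIL-corrected per-meiosis fraction
    lod: float
    distance_cm: float


def _ril_two_locus_R(r: np.ndarray, generation: int) -> np.ndarray:
    """Expected observed recombinant fraction among homozygous F_t RILs.

    Iterates the exact two-locus selfing Markov chain (haplotypes AB, Ab,
    aB, ab; gametes parental with probability (1-r)/2 each, recombinant
    with r/2 each) from the F1 and conditions on homozygosity at both
    loci.  Converges to R = 2r/(1+2r) as t grows.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    n = r.shape[0]
    P = np.zeros((n, 4, 4))
    P[:, 0, 3] = 1.0  # F1 = AB/ab
    for _ in range(generation - 1):
        Q = np.zeros_like(P)
        for h1 in range(4):
            x1, y1 = divmod(h1, 2)
            for h2 in range(4):
                p = P[:, h1, h2]
                if not p.any():
                    continue
                x2, y2 = divmod(h2, 2)
                w = np.zeros((n, 4))
                w[:, h1] += (1.0 - r) / 2.0
                w[:, h2] += (1.0 - r) / 2.0
                w[:, 2 * x1 + y2] += r / 2.0
                w[:, 2 * x2 + y1] += r / 2.0
                Q += p[:, None, None] * w[:, :, None] * w[:, None, :]
        P = Q
    homo = P[:, 0, 0] + P[:, 1, 1] + P[:, 2, 2] + P[:, 3, 3]
    rec = P[:, 1, 1] + P[:, 2, 2]
    return rec / homo


@lru_cache(maxsize=None)
def _ril_inverse_grid(generation: int):
    r_grid = np.linspace(0.0, 0.4999, 2001)
    R_grid = _ril_two_locus_R(r_grid, generation)
    return R_grid, r_grid


def ril_observed_from_meiotic(r: float, generation: int | None = None) -> float:
    """Expected observed fraction R for meiotic r.

    ``generation=None`` gives the selfed-RIL F∞ limit R = 2r/(1+2r);
    a finite generation uses the exact two-locus selfing recursion.
    """
    if generation is None:
        return 2.0 * r / (1.0 + 2.0 * r)
    return float(_ril_two_locus_R(np.array([r]), generation)[0])


def meiotic_from_ril_observed(
    R: float, generation: int | None = None, eps: float = 1e-9
) -> float:
    """Recover the per-meiosis fraction from an observed RIL fraction.

    Inverts the finite-generation recursion (monotone interpolation) when
    ``generation`` is given, else the F∞ closed form r = R/(2(1-R)).
    Capped just below 0.5.
    """
    R = min(R, 0.5)
    if generation is None:
        return min(R / (2.0 * (1.0 - R)), 0.5 - eps)
    R_grid, r_grid = _ril_inverse_grid(generation)
    if R >= R_grid[-1]:
        return 0.5 - eps
    return float(np.interp(R, R_grid, r_grid))


def lod_score(r_hat: float, n_informative: int) -> float:
    """Two-point LOD for an observed recombinant fraction.

    Evaluated at k = round(r_hat * n): LOD = k·log10(R/0.5) +
    (n−k)·log10((1−R)/0.5), with LOD(0.5) = 0 and LOD clipped at 0.
    """
    if not 0.0 <= r_hat <= 0.5:
        raise MappingError(f"r_hat {r_hat} outside [0, 0.5]")
    if n_informative < 1:
        raise MappingError("need at least one informative pair")
    if r_hat == 0.5:
        return 0.0
    n = n_informative
    k = round(r_hat * n)
    lod = (n - k) * math.log10((1.0 - r_hat) / 0.5)
    if k > 0:
        lod += k * math.log10(r_hat / 0.5)
    return max(0.0, lod)


def kosambi_cm(r: float) -> float:
    """Kosambi map distance d = 25 · ln((1 + 2r)/(1 − 2r)) in cM."""
    if not 0.0 <= r < 0.5:
        raise MappingError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def haldane_cm(r: float) -> float:
    """Haldane map distance d = −50 · ln(1 − 2r) in cM (no interference)."""
    if not 0.0 <= r < 0.5:
        raise MappingError(f"recombination fraction {r} outside [0, 0.5)")
    return -50.0 * math.log(1.0 - 2.0 * r)


def estimate_rf(
    calls_a: Sequence[str] | np.ndarray,
    calls_b: Sequence[str] | np.ndarray,
    marker_a: str = "a",
    marker_b: str = "b",
    generation: int | None = None,
) -> TwoPointResult:
    """Two-point recombination estimate between two marker columns.

    Only individuals with homozygous calls at both markers are informative;
    R̂ = recombinants / informative, capped at 0.5, then corrected to the
    per-meiosis r through the selfed-RIL expectation (the exact F_t
    recursion when ``generation`` is given, the F∞ limit otherwise).
    """
    a = np.asarray(calls_a, dtype="<U1")
    b = np.asarray(calls_b, dtype="<U1")
    if a.shape != b.shape:
        raise MappingError("marker columns differ in length")
    informative = np.isin(a, ("A", "B")) & np.isin(b, ("A", "B"))
    n = int(informative.sum())
    if n == 0:
        raise MappingError(
            f"no jointly informative individuals for {marker_a}/{marker_b}"
        )
    rec = int(np.count_nonzero(a[informative] != b[informative]))
    r_hat = min(rec / n, 0.5)
    r = meiotic_from_ril_observed(r_hat, generation)
    return TwoPointResult(
        marker_a, marker_b, n, r_hat, r,
        lod=lod_score(r_hat, n),
        distance_cm=kosambi_cm(r),
    )


def all_pairs(matrix: GenotypeMatrix) -> list[TwoPointResult]:
    """Two-point results for every marker pair (skipping uninformative ones)."""
    out = []
    m = len(matrix.marker_ids)
    for i in range(m):
        for j in range(i + 1, m):
            try:
                out.append(
                    estimate_rf(
                        matrix.calls[i], matrix.calls[j],
                        matrix.marker_ids[i], matrix.marker_ids[j],
                        generation=matrix.generation,
                    )
                )
            except MappingError:
                continue
    return out


def group_markers(
    results: Iterable[TwoPointResult],
    marker_ids: Sequence[str] | None = None,
    lod_threshold: float = 6.0,
    rf_ceiling: float = 0.5,
) -> list[list[str]]:
    """Linkage groups as connected components of the LOD graph.

    Edges join pairs with LOD strictly above ``lod_threshold`` and observed
    fraction below ``rf_ceiling``.  Groups are labelled (and sorted) by
    their smallest member id, so the partition is independent of input
    order.  ``marker_ids`` adds singletons for markers with no edges.
    """
    graph = nx.Graph()
    if marker_ids is not None:
        graph.add_nodes_from(marker_ids)
    for res in results:
        graph.add_nodes_from([res.marker_a, res.marker_b])
        if res.lod > lod_threshold and res.r_hat < rf_ceiling:
            graph.add_edge(res.marker_a, res.marker_b)
    groups = [sorted(c) for c in nx.connected_components(graph)]
    return sorted(groups, key=lambda g: g[0])


def seriate_group(
    group: Sequence[str], results: Iterable[TwoPointResult]
) -> list[str]:
    """Approximate within-group order by greedy nearest-neighbour chaining.

    A convenience view only — two-point seriation, not multipoint ordering.
    """
    members = set(group)
    dist = {}
    for res in results:
        if res.marker_a in members and res.marker_b in members:
            dist[(res.marker_a, res.marker_b)] = res.distance_cm
            dist[(res.marker_b, res.marker_a)] = res.distance_cm
    if not dist:
        return sorted(group)
    start = max(
        members, key=lambda m: max(dist.get((m, o), 0.0) for o in members if o != m)
    )
    order = [start]
    remaining = members - {start}
    while remaining:
        nxt = min(remaining, key=lambda m: dist.get((order[-1], m), math.inf))
        order.append(nxt)
        remaining.discard(nxt)
    return order


def results_to_table(results: Iterable[TwoPointResult]) -> pd.DataFrame:
    rows = [
        (r.marker_a, r.marker_b, r.n_informative, r.r_hat, r.r_meiotic,
         r.lod, r.distance_cm)
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["marker_a", "marker_b", "n_informative", "r_hat",
                 "r_meiotic", "lod", "distance_cm"],
    )
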