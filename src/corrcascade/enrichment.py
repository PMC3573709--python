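"""Over-representation analysis against GMT gene-set collections.

The test is the upper-tail hypergeometric probability of observing at least
the seen overlap between a query gene set and an annotation term within a
background universe, with Benjamini-Hochberg step-up adjustment across terms.
An EASE-style penalized variant (overlap reduced by one, as popularized by
the DAVID annotation tool) is available as an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "hypergeom_upper", "bh_adjust", "enrich"]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    members: frozenset[str]


class GeneSetCollection:
    """Named gene sets keyed by unique term id (GMT-backed)."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.term_id in self._sets:
                raise ValueError(f"duplicate term id {gs.term_id!r}")
            if not gs.members:
                raise ValueError(f"term {gs.term_id!r} has no members")
            self._sets[gs.term_id] = gs

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self._sets[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._sets

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        return cls(GeneSet(t, t, frozenset(m)) for t, m in d.items())

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets = []
        with open(path, "rt", encoding="utf-8") as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: GMT line needs term, "
                                     "description and >=1 member")
                members = frozenset(p for p in parts[2:] if p.strip())
                sets.append(GeneSet(parts[0], parts[1], members))
        return cls(sets)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "wt", encoding="utf-8", newline="") as fh:
            for gs in self:
                fh.write("\t".join([gs.term_id, gs.name, *sorted(gs.members)]) + "\n")


def hypergeom_upper(k: int, K: int, n: int, N: int, *, ease: bool = False) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``X`` counts white draws when ``n`` balls are drawn without replacement
    from an urn of ``N`` with ``K`` white.  With ``ease=True`` the observed
    overlap is penalized by one (P(X >= k-1) for k > 0), the conservative
    EASE-score convention.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if K > N or n > N or k > min(K, n):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if ease and k > 0:
        k = k - 1
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return arr
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.025,
    *,
    ease: bool = False,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each term of ``collection``.

    Query members outside the universe are dropped with a warning; term
    memberships are intersected with the universe.  Rows (one per term with
    overlap >= 1) are sorted by adjusted then raw probability; ``significant``
    flags adjusted values below ``alpha``.
    """
    universe = set(universe)
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(f"dropping {len(outside)} query genes outside the universe",
                      stacklevel=2)
        query &= universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")
    N, n = len(universe), len(query)
    rows = []
    for gs in collection:
        members = gs.members & universe
        overlap = members & query
        if not overlap:
            continue
        p = hypergeom_upper(len(overlap), len(members), n, N, ease=ease)
        rows.append((gs.term_id, gs.name, len(overlap), len(members), p))
    out = pd.DataFrame(rows, columns=["term", "name", "count", "universe_count", "p"])
    if out.empty:
        out["p_adj"] = out["significant"] = []
        return out
    out["p_adj"] = bh_adjust(out["p"])
    out["significant"] = out["p_adj"] < alpha
    out = out.sort_values(["p_adj", "p"], kind="mergesort").reset_index(drop=True)
    return out
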