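"""Hypergeometric source enrichment over compound→source annotations.

Given a set of screening hits and a mapping from compounds to their sources
(medicinal herbs, targets, or any categorical annotation), each source is
tested for over-representation among the hits with the hypergeometric
upper-tail probability P(X ≥ k), where the universe of size N contains K
compounds of the source and n hits were drawn. P-values are adjusted across
all tested sources with Benjamini–Hochberg. By default the universe is the
set of compounds carrying at least one mapping; pass ``universe`` explicitly
(e.g. the full screened library) to override.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["SourceMapping", "enrich_sources", "bh_adjust"]


@dataclass
class SourceMapping:
    """compound id → set of source labels, with optional per-source metadata."""

    entries: Dict[str, Set[str]]
    source_meta: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        for cid, sources in self.entries.items():
            if any(not s for s in sources):
                raise ValueError(f"compound {cid!r} has an empty source label")

    @property
    def sources(self) -> Set[str]:
        out: Set[str] = set()
        for s in self.entries.values():
            out |= s
        return out

    def members_of(self, source: str) -> Set[str]:
        return {cid for cid, ss in self.entries.items() if source in ss}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SourceMapping":
        """Build from a (compound_id, source[, family, genus]) table."""
        entries: Dict[str, Set[str]] = {}
        meta: Dict[str, dict] = {}
        for row in df.itertuples(index=False):
            cid, source = str(row.compound_id), str(row.source)
            entries.setdefault(cid, set()).add(source)
            extra = {
                k: getattr(row, k)
                for k in ("family", "genus")
                if hasattr(row, k) and pd.notna(getattr(row, k))
            }
            if extra:
                meta.setdefault(source, {}).update(extra)
        return cls(entries=entries, source_meta=meta)


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_sources(
    hits: Iterable[str],
    mapping: SourceMapping,
    universe: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every source among the hits.

    Returns one row per source — columns ``source, k, K, n, N, p, p_adj,
    enriched`` (+ any source metadata) — sorted ascending by adjusted p-value.
    All sources are retained; ``enriched`` marks p_adj < alpha. ``hits`` must
    be a subset of the universe.
    """
    if universe is None:
        universe_set = set(mapping.entries)
    else:
        universe_set = {str(u) for u in universe}
    if not universe_set:
        raise ValueError("universe is empty")
    hit_set = {str(h) for h in hits}
    stray = hit_set - universe_set
    if stray:
        raise ValueError(
            f"{len(stray)} hit(s) outside the universe, e.g. {sorted(stray)[:3]}"
        )
    N = len(universe_set)
    n = len(hit_set)
    rows = []
    for source in sorted(mapping.sources):
        members = mapping.members_of(source) & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & hit_set)
        # P(X >= k) for X ~ Hypergeometric(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        row = {"source": source, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)}
        row.update(mapping.source_meta.get(source, {}))
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adj"] = bh_adjust(table["p"])
    table["enriched"] = (table["p_adj"] < alpha) & (table["k"] > 0)
    return table.sort_values(["p_adj", "p", "source"], kind="stable").reset_index(
        drop=True
    )
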