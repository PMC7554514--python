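"""Hypergeometric pathway over-representation analysis.

Given a query gene list (e.g. DEGs), a collection of pathway gene sets and
a gene universe of size N, each pathway of size K overlapping the query
(size n) in k genes is scored by the upper-tail hypergeometric probability
P(X >= k). Adjusted q-values (Benjamini–Hochberg) determine significance,
conventionally at q <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .tag_dge import bh_fdr

__all__ = [
    "GeneSetCollection",
    "hypergeom_p",
    "enrich",
    "top_k_overlap",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSetCollection:
    """Pathway -> gene-set mapping over a fixed gene universe."""

    sets: dict[str, set]
    universe: set
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} is empty")
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"pathway {pid!r} has genes outside the universe: "
                    f"{sorted(extra)[:3]}..."
                )

    @classmethod
    def from_sets(cls, sets: dict[str, set], universe=None, names=None):
        """Build a collection; universe defaults to the union of all sets."""
        if universe is None:
            universe = set().union(*sets.values()) if sets else set()
        return cls(sets, set(universe), names or {})


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts pathway genes among ``n`` draws without replacement from a
    universe of ``N`` genes of which ``K`` belong to the pathway.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError("need 0 <= k <= min(n, K)")
    if n > N or K > N:
        raise ValueError("query and pathway sizes cannot exceed the universe")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(query, collection: GeneSetCollection, q_max: float = 0.05) -> pd.DataFrame:
    """Over-representation of ``query`` in every pathway with overlap > 0.

    Query genes outside the universe are dropped (with a warning via the
    returned attrs). Returns a frame sorted by (q, p, pathway_id) with
    columns pathway_id, name, k, n, K, N, p, q, significant.
    """
    query = set(query)
    dropped = query - collection.universe
    query &= collection.universe
    N = len(collection.universe)
    n = len(query)
    rows = []
    for pid, genes in collection.sets.items():
        k = len(query & genes)
        if k == 0:
            continue
        rows.append(
            {
                "pathway_id": pid,
                "name": collection.names.get(pid, pid),
                "k": k,
                "n": n,
                "K": len(genes),
                "N": N,
                "p": hypergeom_p(k, n, len(genes), N),
            }
        )
    if not rows:
        out = pd.DataFrame(
            columns=["pathway_id", "name", "k", "n", "K", "N", "p", "q", "significant"]
        )
        out.attrs["dropped"] = sorted(dropped)
        return out
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] <= q_max
    out = out.sort_values(["q", "p", "pathway_id"], kind="stable").reset_index(drop=True)
    out.attrs["dropped"] = sorted(dropped)
    return out


def top_k_overlap(list_a, list_b, k: int = 20) -> int:
    """Number of pathway ids shared by the top-k of two ranked lists."""
    a, b = list(list_a), list(list_b)
    if k > len(a) or k > len(b):
        raise ValueError("k exceeds a list length")
    return len(set(a[:k]) & set(b[:k]))


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from a GMT file (id, description, genes...)."""
    sets: dict[str, set] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
            names[parts[0]] = parts[1]
    return GeneSetCollection.from_sets(sets, names=names)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(collection.sets):
            name = collection.names.get(pid, pid)
            genes = "\t".join(sorted(collection.sets[pid]))
            fh.write(f"{pid}\t{name}\t{genes}\n")
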