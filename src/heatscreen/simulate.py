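"""Synthetic datasets with known ground truth for every pipeline stage.

Each generator emulates the statistical structure of one input of the
heat-stress screening pipeline — two-library tag counts, multi-sample
count matrices, promoters with planted DRE elements, proteins with
planted domain copies, qPCR Ct tables encoding known fold changes,
multinomial injury tallies, and alignments evolved along a tree — and
ships a machine-readable truth table so recovery can be scored.

Randomness: every generator draws from a stream derived from one global
seed plus a generator-specific stream id, so adding a generator never
perturbs the draws of another. Identical seed and configuration give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import Node
from .seq_screen import reverse_complement
from .tag_dge import TagLibraryPair
from .count_de import CountMatrix

__all__ = [
    "SimConfig",
    "sim_tag_libraries",
    "sim_count_matrix",
    "sim_promoters",
    "sim_proteins",
    "sim_ct_table",
    "sim_injury_tallies",
    "sim_alignment",
]

# fixed per-generator stream ids (see module docstring)
_STREAMS = {
    "tags": 1,
    "matrix": 2,
    "promoters": 3,
    "proteins": 4,
    "ct": 5,
    "injury": 6,
    "alignment": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


@dataclass(frozen=True)
class SimConfig:
    """Shared knobs of the count simulators.

    ``effect_log2`` is the mean |log2 fold change| planted in DE genes;
    ``dispersion`` is the gamma-Poisson overdispersion (variance =
    mu + dispersion * mu^2; 0 gives pure Poisson, matching the tag-DGE
    model assumption).
    """

    n_genes: int = 10_000
    de_fraction: float = 0.1
    effect_log2: float = 2.0
    library_sizes: tuple[int, ...] = (1_000_000, 1_000_000)
    dispersion: float = 0.0
    seed: int = 0
    n_samples_per_group: int = 3

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if any(s <= 0 for s in self.library_sizes):
            raise ValueError("library sizes must be positive")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")


def _truth(rng: np.random.Generator, config: SimConfig) -> pd.DataFrame:
    gene_ids = [f"gene{i:05d}" for i in range(config.n_genes)]
    is_de = rng.random(config.n_genes) < config.de_fraction
    signs = rng.choice([-1.0, 1.0], size=config.n_genes)
    lfc = np.where(is_de, signs * config.effect_log2, 0.0)
    return pd.DataFrame({"gene_id": gene_ids, "is_de": is_de, "true_log2fc": lfc})


def _base_means(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    # log-normal expression profile, renormalized to proportions
    raw = rng.lognormal(mean=0.0, sigma=1.3, size=config.n_genes)
    return raw / raw.sum()


def _draw_counts(rng, mu, dispersion):
    if dispersion == 0:
        return rng.poisson(mu)
    # gamma-Poisson: shape 1/phi, scale mu*phi => var = mu + phi mu^2
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def sim_tag_libraries(config: SimConfig) -> tuple[TagLibraryPair, pd.DataFrame]:
    """Two tag libraries with a planted DE fraction.

    Library-1 means are the expression profile scaled to the first
    library size; DE genes have their library-2 means multiplied by
    2^true_log2fc. Realized totals N1, N2 are the column sums.
    """
    if len(config.library_sizes) != 2:
        raise ValueError("tag simulation needs exactly two library sizes")
    rng = _rng(config.seed, "tags")
    truth = _truth(rng, config)
    props = _base_means(rng, config)
    mu1 = props * config.library_sizes[0]
    mu2 = props * config.library_sizes[1] * np.power(2.0, truth["true_log2fc"].to_numpy())
    x = _draw_counts(rng, mu1, config.dispersion)
    y = _draw_counts(rng, mu2, config.dispersion)
    counts = pd.DataFrame({"gene_id": truth["gene_id"], "x": x, "y": y})
    return TagLibraryPair.from_counts(counts), truth


def sim_count_matrix(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Two-group count matrix with gene lengths and a planted DE fraction."""
    rng = _rng(config.seed, "matrix")
    truth = _truth(rng, config)
    props = _base_means(rng, config)
    lengths = rng.integers(300, 5000, size=config.n_genes)
    k = config.n_samples_per_group
    depth = config.library_sizes[0]
    cols, data, groups = [], [], {}
    shift = np.power(2.0, truth["true_log2fc"].to_numpy())
    for g, label in enumerate(("A", "B")):
        mu = props * depth * (shift if g == 1 else 1.0)
        for s in range(k):
            name = f"{label}{s + 1}"
            cols.append(name)
            groups[name] = label
            data.append(_draw_counts(rng, mu, config.dispersion))
    counts = pd.DataFrame(
        np.column_stack(data), index=truth["gene_id"].to_numpy(), columns=cols
    ).astype(float)
    counts.index.name = "gene_id"
    matrix = CountMatrix(
        counts, pd.Series(lengths, index=counts.index, dtype=float), groups
    )
    # truth log2fc is group B over group A in this design
    return matrix, truth


def sim_promoters(
    n: int,
    length: int = 2000,
    planted: tuple[str, int, str] | None = None,
    seed: int = 0,
    gc: float = 0.5,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random promoters with an optionally planted element.

    ``planted`` is (element, position, strand); the element (reverse-
    complemented for '-') replaces the background at ``position`` in every
    promoter. Returns the sequences and a truth table of planted
    coordinates (0-based half-open, forward strand).
    """
    p_at = (1 - gc) / 2
    p_gc = gc / 2
    rng = _rng(seed, "promoters")
    seqs: dict[str, str] = {}
    rows = []
    for i in range(n):
        arr = rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])
        seq = "".join(arr)
        if planted is not None:
            element, pos, strand = planted
            if pos + len(element) > length:
                raise ValueError("planted element does not fit in the promoter")
            ins = element if strand == "+" else reverse_complement(element)
            seq = seq[:pos] + ins + seq[pos + len(element):]
            rows.append(
                {
                    "seq_id": f"prom{i:05d}",
                    "element": element,
                    "start": pos,
                    "end": pos + len(element),
                    "strand": strand,
                }
            )
        seqs[f"prom{i:05d}"] = seq
    truth = pd.DataFrame(rows, columns=["seq_id", "element", "start", "end", "strand"])
    return seqs, truth


_AA = "ACDEFGHIKLMNPQRSTVWY"


def sim_proteins(
    domain_copies: list[int],
    consensus: str,
    mutation_rate: float = 0.0,
    flank_len: int = 80,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random proteins with 0, 1 or 2 planted (mutated) consensus copies.

    One protein per entry of ``domain_copies``; each planted copy has
    every residue independently replaced with a random different amino
    acid at ``mutation_rate``. Copies are separated by random flanks of
    ``flank_len`` residues.
    """
    if not 0.0 <= mutation_rate <= 0.5:
        raise ValueError("mutation_rate must lie in [0, 0.5]")
    rng = _rng(seed, "proteins")
    seqs: dict[str, str] = {}
    rows = []
    for i, copies in enumerate(domain_copies):
        if copies not in (0, 1, 2):
            raise ValueError("domain copies must be 0, 1 or 2")
        parts = ["".join(rng.choice(list(_AA), size=flank_len))]
        for _ in range(copies):
            domain = list(consensus)
            for j in range(len(domain)):
                if rng.random() < mutation_rate:
                    choices = [a for a in _AA if a != domain[j]]
                    domain[j] = choices[rng.integers(len(choices))]
            parts.append("".join(domain))
            parts.append("".join(rng.choice(list(_AA), size=flank_len)))
        pid = f"prot{i:04d}"
        seqs[pid] = "".join(parts)
        rows.append({"prot_id": pid, "n_domains": copies})
    return seqs, pd.DataFrame(rows)


def sim_ct_table(
    true_rq: dict[str, float],
    calibrator: str,
    noise_sd: float = 0.0,
    n_reps: int = 3,
    base_ct_target: float = 26.0,
    base_ct_ref: float = 18.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table encoding known relative quantities per sample.

    The target Ct of sample s is shifted by -log2(true_rq[s] /
    true_rq[calibrator]); the reference gene is constant. Gaussian noise
    of ``noise_sd`` cycles is added per replicate well.
    """
    if calibrator not in true_rq:
        raise ValueError("calibrator must appear in true_rq")
    if any(v <= 0 for v in true_rq.values()):
        raise ValueError("relative quantities must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = _rng(seed, "ct")
    rows = []
    cal = true_rq[calibrator]
    for sample, rq in true_rq.items():
        shift = -np.log2(rq / cal)
        for gene, base in (("target", base_ct_target + shift), ("reference", base_ct_ref)):
            for rep in range(n_reps):
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "rep": rep + 1,
                        "ct": base + rng.normal(0.0, noise_sd) if noise_sd else base,
                    }
                )
    return pd.DataFrame(rows)


def sim_injury_tallies(
    n_plants: int, level_probs, max_level: int = 3, seed: int = 0
) -> np.ndarray:
    """Multinomial plant counts over injury levels 0..max_level."""
    probs = np.asarray(level_probs, dtype=float)
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    if len(probs) != max_level + 1:
        raise ValueError("level_probs must cover levels 0..max_level")
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("level_probs must sum to 1")
    rng = _rng(seed, "injury")
    return rng.multinomial(n_plants, probs)


def _sim_along(node: Node, seq: np.ndarray, rng, rate_to_prob) -> dict[str, str]:
    out: dict[str, str] = {}
    for child, bl in node.children:
        p_sub = rate_to_prob(bl)
        mutated = seq.copy()
        hit = rng.random(len(seq)) < p_sub
        if hit.any():
            # Jukes-Cantor: substitute with one of the three other bases
            alt = (mutated[hit] + rng.integers(1, 4, size=hit.sum())) % 4
            mutated[hit] = alt
        if child.is_leaf:
            out[child.name] = "".join("ACGT"[b] for b in mutated)
        else:
            out.update(_sim_along(child, mutated, rng, rate_to_prob))
    return out


def sim_alignment(tree: Node, seq_len: int, seed: int = 0) -> dict[str, str]:
    """Sequences evolved site-independently along a tree (Jukes–Cantor).

    Branch lengths are expected substitutions per site; the probability
    of a site differing across a branch of length t is (3/4)(1 - e^(-4t/3)).
    Zero branch lengths give identical sequences.
    """
    if seq_len <= 0:
        raise ValueError("seq_len must be positive")
    rng = _rng(seed, "alignment")
    root = rng.integers(0, 4, size=seq_len)

    def rate_to_prob(t: float) -> float:
        return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))

    return _sim_along(tree, root, rng, rate_to_prob)
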