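"""Reed-Solomon dye-sequence codebooks for combinatorial FISH.

Each gene is identified over ``n_rounds`` imaging rounds by the sequence of
fluorescent dyes it lights up in.  Dye sequences are codewords of a
Reed-Solomon code over the prime field GF(``n_dyes``): gene integer ``g`` is
written in base ``n_dyes`` as digits ``(g2, g1, g0)`` and the dye shown in
round ``r`` is the polynomial evaluation

    D(g, r) = (g2 * r**2 + g1 * r + g0) mod n_dyes.

Two distinct polynomials of degree <= 2 over a prime field agree at no more
than 2 points, so with 7 rounds and 7 dyes any two codewords differ in at
least 5 rounds.  Constant codewords (``g < n_dyes``) are indistinguishable
from fixed background fluorescence and are never assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Codebook",
    "assign_dye_sequences",
    "is_valid_code",
    "dye_sequence_for_integer",
    "enumerate_bridge_probes",
    "min_pairwise_distance",
    "read_codebook_csv",
    "write_codebook_csv",
]


class CodebookCapacityError(ValueError):
    """More genes requested than the code space holds."""


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    return all(n % k for k in range(2, int(n**0.5) + 1))


def dye_sequence_for_integer(g: int, n_rounds: int, n_dyes: int) -> tuple[int, ...]:
    """Evaluate the degree-<=2 code polynomial of gene integer ``g``.

    ``g`` is expanded in base ``n_dyes`` as ``g2*n_dyes**2 + g1*n_dyes + g0``
    and the dye for round ``r`` is ``(g2*r*r + g1*r + g0) % n_dyes``.
    """
    if not 0 <= g < n_dyes**3:
        raise ValueError(f"gene integer {g} outside [0, {n_dyes ** 3})")
    g2, rem = divmod(g, n_dyes**2)
    g1, g0 = divmod(rem, n_dyes)
    return tuple((g2 * r * r + g1 * r + g0) % n_dyes for r in range(n_rounds))


def is_valid_code(dye_sequence: Sequence[int]) -> bool:
    """A code is usable iff it is not the same dye in every round."""
    seq = list(dye_sequence)
    return any(d != seq[0] for d in seq[1:])


@dataclass(frozen=True)
class Codebook:
    """Mapping gene -> dye-per-round codeword.

    Attributes
    ----------
    n_rounds, n_dyes:
        Code geometry; ``n_dyes`` is the (prime) field modulus.
    entries:
        DataFrame with columns ``gene_name``, ``gene_index`` and one integer
        dye column per round (``r0`` ... ``r{n_rounds-1}``).
    """

    n_rounds: int
    n_dyes: int
    entries: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        seqs = self.dye_sequences()
        if len(set(map(tuple, seqs.tolist()))) != len(seqs):
            raise ValueError("duplicate dye sequences in codebook")
        if self.entries["gene_index"].duplicated().any():
            raise ValueError("duplicate gene indexes in codebook")
        for row in seqs:
            if not is_valid_code(row):
                raise ValueError("constant dye sequence in codebook")

    @property
    def n_genes(self) -> int:
        return len(self.entries)

    @property
    def gene_names(self) -> list[str]:
        return self.entries["gene_name"].tolist()

    def dye_sequences(self) -> np.ndarray:
        """(n_genes, n_rounds) integer array of dye assignments."""
        cols = [f"r{r}" for r in range(self.n_rounds)]
        return self.entries[cols].to_numpy(dtype=int)


def assign_dye_sequences(
    gene_names: Sequence[str], n_rounds: int = 7, n_dyes: int = 7
) -> Codebook:
    """Assign each gene the next available non-constant Reed-Solomon codeword.

    Genes receive ascending integers in input order, starting from the
    smallest ``g`` whose codeword varies across rounds (``g = n_dyes`` for
    the default scheme, because ``g < n_dyes`` encodes a constant
    polynomial).

    Raises
    ------
    ValueError
        If ``n_dyes`` is not prime or ``n_rounds > n_dyes``.
    CodebookCapacityError
        If more genes are requested than there are non-constant codewords
        (``n_dyes**3 - n_dyes``).
    """
    gene_names = list(gene_names)
    if not _is_prime(n_dyes):
        raise ValueError(f"n_dyes must be prime, got {n_dyes}")
    if not 1 <= n_rounds <= n_dyes:
        raise ValueError(
            f"n_rounds must be in [1, n_dyes={n_dyes}] for distinct "
            f"evaluation points, got {n_rounds}"
        )
    capacity = n_dyes**3 - n_dyes
    if len(gene_names) > capacity:
        raise CodebookCapacityError(
            f"{len(gene_names)} genes exceed the {capacity} usable codewords "
            f"of the {n_dyes}-dye scheme"
        )
    if len(set(gene_names)) != len(gene_names):
        raise ValueError("gene names must be unique")

    rows = []
    g = 0
    for name in gene_names:
        while True:
            seq = dye_sequence_for_integer(g, n_rounds, n_dyes)
            g += 1
            if is_valid_code(seq):
                break
        rows.append((name, g - 1, *seq))

    cols = ["gene_name", "gene_index"] + [f"r{r}" for r in range(n_rounds)]
    entries = pd.DataFrame(rows, columns=cols)
    return Codebook(n_rounds=n_rounds, n_dyes=n_dyes, entries=entries)


def enumerate_bridge_probes(codebook: Codebook) -> pd.DataFrame:
    """One bridge probe per (gene, round): the oligo linking the gene's
    barcode to that round's dye probe.  Row count is n_genes * n_rounds."""
    seqs = codebook.dye_sequences()
    names = codebook.gene_names
    rows = [
        (names[i], r, int(seqs[i, r]))
        for i in range(codebook.n_genes)
        for r in range(codebook.n_rounds)
    ]
    return pd.DataFrame(rows, columns=["gene_name", "round", "dye"])


def min_pairwise_distance(codebook: Codebook) -> int:
    """Minimum Hamming distance between any two dye sequences."""
    if codebook.n_genes < 2:
        raise ValueError("need at least 2 genes to compute pairwise distance")
    seqs = codebook.dye_sequences()
    best = codebook.n_rounds
    for a, b in combinations(range(len(seqs)), 2):
        d = int((seqs[a] != seqs[b]).sum())
        if d < best:
            best = d
    return best


def write_codebook_csv(codebook: Codebook, path: str | Path) -> None:
    codebook.entries.to_csv(path, index=False)


def read_codebook_csv(path: str | Path, n_dyes: int | None = None) -> Codebook:
    entries = pd.read_csv(path)
    round_cols = [c for c in entries.columns if c.startswith("r") and c[1:].isdigit()]
    n_rounds = len(round_cols)
    if n_dyes is None:
        # modulus is the smallest prime covering the observed dyes
        n_dyes = max(int(entries[round_cols].to_numpy().max()) + 1, 2)
        while not _is_prime(n_dyes):
            n_dyes += 1
    return Codebook(n_rounds=n_rounds, n_dyes=n_dyes, entries=entries)
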