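"""Reference-relative mutation coordinates for protein sequence design.

Every candidate sequence is described as a set of single-residue
substitutions relative to a fixed reference (wildtype) protein.  For a
reference of length ``L`` there are ``M = 19 L`` possible substitutions;
the *k*-mutation shell ``S_k`` contains ``C(L, k) * 19**k`` sequences
(``k`` substitutions at ``k`` distinct sites).  This module owns the
bijection between substitutions and their flat index ``m`` in ``[0, M)``,
the ``A123V`` string notation, shell enumeration, and FASTA input.

Coordinates are 1-based in all user-facing notation (``A123V``) and
0-based internally; conversions are confined to parse/format.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from Bio import SeqIO

#: The 20 canonical amino acids, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

__all__ = [
    "AMINO_ACIDS",
    "ReferenceSequence",
    "Mutation",
    "VariantSpec",
    "enumerate_single_mutations",
    "apply_mutations",
    "shell_size",
    "parse_mutation_string",
    "format_mutation",
    "parse_variant_string",
    "format_variant",
    "enumerate_shell",
    "read_reference_fasta",
]


@dataclass(frozen=True)
class ReferenceSequence:
    """A fixed wildtype protein sequence over the 20-letter alphabet."""

    residues: str
    id: str = "ref"

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("reference sequence must have length >= 1")
        for i, aa in enumerate(self.residues):
            if aa not in _AA_SET:
                raise ValueError(
                    f"non-canonical residue {aa!r} at position {i + 1}; "
                    f"the alphabet is {AMINO_ACIDS}"
                )

    @property
    def L(self) -> int:
        return len(self.residues)

    @property
    def n_mutations(self) -> int:
        """Number of possible single substitutions, M = 19 L."""
        return 19 * self.L

    # ---- index <-> (site, to_aa) bijection -------------------------------
    def mutation_to_index(self, mut: "Mutation") -> int:
        """Flat 0-based index of a substitution: by site, then alphabetical."""
        ref_aa = self.residues[mut.site - 1]
        if mut.to_aa == ref_aa:
            raise ValueError(f"{mut} does not change residue {ref_aa} at site {mut.site}")
        rank = AMINO_ACIDS.index(mut.to_aa)
        if rank > AMINO_ACIDS.index(ref_aa):
            rank -= 1
        return (mut.site - 1) * 19 + rank

    def index_to_mutation(self, m: int) -> "Mutation":
        if not 0 <= m < self.n_mutations:
            raise ValueError(f"mutation index {m} out of range [0, {self.n_mutations})")
        site0, rank = divmod(m, 19)
        ref_aa = self.residues[site0]
        alternatives = [aa for aa in AMINO_ACIDS if aa != ref_aa]
        return Mutation(site=site0 + 1, to_aa=alternatives[rank])

    def site_of_index(self, m: int) -> int:
        """0-based site of a flat mutation index (19 indices per site)."""
        return m // 19


@dataclass(frozen=True, order=True)
class Mutation:
    """A single substitution: 1-based ``site`` mutated to ``to_aa``."""

    site: int
    to_aa: str

    def __post_init__(self) -> None:
        if self.site < 1:
            raise ValueError(f"site {self.site} must be >= 1 (1-based)")
        if self.to_aa not in _AA_SET:
            raise ValueError(f"target residue {self.to_aa!r} is not a canonical amino acid")


@dataclass(frozen=True)
class VariantSpec:
    """An unordered set of substitutions at distinct sites; k=0 is the reference.

    The canonical key (mutations sorted by site then target residue, joined
    with ``+``) is order-independent and is used for caching and
    tie-breaking throughout the package.
    """

    mutations: tuple[Mutation, ...] = field(default=())

    def __post_init__(self) -> None:
        muts = tuple(sorted(set(self.mutations)))
        sites = [m.site for m in muts]
        if len(set(sites)) != len(sites):
            dup = next(s for s in sites if sites.count(s) > 1)
            raise ValueError(f"duplicate mutated site {dup}: mutations must occupy distinct sites")
        object.__setattr__(self, "mutations", muts)

    @property
    def k(self) -> int:
        return len(self.mutations)

    def canonical_key(self, ref: ReferenceSequence) -> str:
        return format_variant(self, ref)

    def indices(self, ref: ReferenceSequence) -> tuple[int, ...]:
        return tuple(ref.mutation_to_index(m) for m in self.mutations)

    @classmethod
    def from_indices(cls, ref: ReferenceSequence, indices: Sequence[int]) -> "VariantSpec":
        return cls(tuple(ref.index_to_mutation(m) for m in indices))


def enumerate_single_mutations(ref: ReferenceSequence) -> list[Mutation]:
    """All M = 19 L single substitutions, ordered by site then target residue.

    The list position of each mutation equals its flat index
    ``ref.mutation_to_index``.
    """
    out: list[Mutation] = []
    for site0, ref_aa in enumerate(ref.residues):
        for aa in AMINO_ACIDS:
            if aa != ref_aa:
                out.append(Mutation(site=site0 + 1, to_aa=aa))
    return out


def apply_mutations(ref: ReferenceSequence, variant: VariantSpec) -> str:
    """The full mutated sequence; a plain substitution, hence idempotent."""
    residues = list(ref.residues)
    for mut in variant.mutations:
        if not 1 <= mut.site <= ref.L:
            raise ValueError(f"site {mut.site} out of range [1, {ref.L}]")
        if ref.residues[mut.site - 1] == mut.to_aa:
            raise ValueError(
                f"mutation at site {mut.site} to {mut.to_aa} equals the reference residue"
            )
        residues[mut.site - 1] = mut.to_aa
    return "".join(residues)


def shell_size(L: int, k: int) -> int:
    """Exact size of the k-mutation shell, C(L, k) * 19**k."""
    if k < 1 or k > L:
        raise ValueError(f"k must satisfy 1 <= k <= L; got k={k}, L={L}")
    return math.comb(L, k) * 19**k


def parse_mutation_string(text: str, ref: ReferenceSequence) -> Mutation:
    """Parse ``<refAA><site><altAA>`` (e.g. ``A123V``), validating the reference residue."""
    text = text.strip()
    if len(text) < 3 or not text[1:-1].isdigit():
        raise ValueError(f"malformed mutation string {text!r}; expected e.g. 'A123V'")
    ref_aa, site, to_aa = text[0], int(text[1:-1]), text[-1]
    if not 1 <= site <= ref.L:
        raise ValueError(f"site {site} out of range [1, {ref.L}]")
    actual = ref.residues[site - 1]
    if ref_aa != actual:
        raise ValueError(
            f"reference mismatch in {text!r}: position {site} is {actual}, not {ref_aa}"
        )
    if to_aa == actual:
        raise ValueError(f"{text!r} does not mutate: target equals the reference residue")
    return Mutation(site=site, to_aa=to_aa)


def format_mutation(mut: Mutation, ref: ReferenceSequence) -> str:
    return f"{ref.residues[mut.site - 1]}{mut.site}{mut.to_aa}"


def parse_variant_string(text: str, ref: ReferenceSequence) -> VariantSpec:
    """Parse a ``+``-joined multi-mutant string; the empty string is the reference."""
    text = text.strip()
    if not text:
        return VariantSpec(())
    return VariantSpec(tuple(parse_mutation_string(t, ref) for t in text.split("+")))


def format_variant(variant: VariantSpec, ref: ReferenceSequence) -> str:
    return "+".join(format_mutation(m, ref) for m in variant.mutations)


def enumerate_shell(ref: ReferenceSequence, k: int) -> Iterator[VariantSpec]:
    """Yield every variant of the exact-k shell S_k in deterministic order."""
    if k < 1 or k > ref.L:
        raise ValueError(f"k must satisfy 1 <= k <= L; got k={k}, L={ref.L}")
    site_alternatives = [
        [aa for aa in AMINO_ACIDS if aa != ref_aa] for ref_aa in ref.residues
    ]
    for sites in itertools.combinations(range(ref.L), k):
        for targets in itertools.product(*(site_alternatives[s] for s in sites)):
            yield VariantSpec(
                tuple(Mutation(site=s + 1, to_aa=aa) for s, aa in zip(sites, targets))
            )


def shell_index_matrix(ref: ReferenceSequence, k: int):
    """The exact-k shell as an (n, k) array of flat mutation indices.

    Rows follow the same deterministic order as :func:`enumerate_shell`
    (site combinations lexicographic, then target residues alphabetical
    per site), without materializing VariantSpec objects.
    """
    import numpy as np

    if k < 1 or k > ref.L:
        raise ValueError(f"k must satisfy 1 <= k <= L; got k={k}, L={ref.L}")
    # rank r in [0, 19) at a site maps to flat index site0 * 19 + r
    ranks = np.stack(
        np.meshgrid(*([np.arange(19)] * k), indexing="ij"), axis=-1
    ).reshape(-1, k)
    blocks = []
    for sites in itertools.combinations(range(ref.L), k):
        offsets = np.asarray(sites, dtype=np.intp) * 19
        blocks.append(offsets[None, :] + ranks)
    return np.concatenate(blocks, axis=0)


def read_reference_fasta(path) -> ReferenceSequence:
    """Read the reference from a FASTA file; the first record is used."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} contains {len(records)} records; using the first ({records[0].id})",
            stacklevel=2,
        )
    rec = records[0]
    return ReferenceSequence(residues=str(rec.seq).upper(), id=rec.id)
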