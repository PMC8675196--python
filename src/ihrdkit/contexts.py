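"""Canonical 96 trinucleotide substitution contexts.

Single-base substitutions are reported on the pyrimidine strand: a mutation
whose reference base is a purine (A or G) is reverse-complemented together
with its flanking bases before classification.  The fixed ordering is the
COSMIC convention: substitution blocks C>A, C>G, C>T, T>A, T>C, T>G, and
within each block the 5' flanking base varies first (A, C, G, T), then the
3' base (A, C, G, T).  Every catalog, signature matrix and TSV emitted by
this package uses this ordering.
"""

from __future__ import annotations

BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _build_contexts() -> tuple[str, ...]:
    keys = []
    for sub in SUBSTITUTIONS:
        for five in BASES:
            for three in BASES:
                keys.append(f"{five}[{sub}]{three}")
    return tuple(keys)


CONTEXTS_96: tuple[str, ...] = _build_contexts()
CONTEXT_INDEX: dict[str, int] = {k: i for i, k in enumerate(CONTEXTS_96)}


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence {seq!r}") from exc


def context_key(ref: str, alt: str, trinucleotide: str) -> str:
    """Classify one SNV into its pyrimidine-strand context key.

    Parameters
    ----------
    ref, alt : str
        Single reference and alternate bases.
    trinucleotide : str
        The 5'->3' reference trinucleotide centred on the variant position
        (middle base must equal ``ref``).

    Returns
    -------
    str
        A key of the form ``"X[R>A]Y"`` with R in {C, T}.

    Raises
    ------
    ValueError
        For non-SNVs, unknown characters, or a trinucleotide whose middle
        base disagrees with ``ref``.
    """
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"unknown allele characters: {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"reference and alternate allele identical: {ref}")
    tri = trinucleotide.upper()
    if len(tri) != 3:
        raise ValueError(f"trinucleotide context must have length 3: {tri!r}")
    if any(b not in BASES for b in tri):
        raise ValueError(f"unknown context characters: {tri!r}")
    if tri[1] != ref:
        raise ValueError(
            f"context middle base {tri[1]!r} does not match ref allele {ref!r}"
        )
    if ref in ("A", "G"):  # purine strand -> flip to pyrimidine strand
        tri = reverse_complement(tri)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"
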