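"""Sample-specific variant-peptide database construction.

SNVs and small indels observed in expressed transcripts (FPKM > 1) are
applied to the coding sequence and translated.  Stop-gain variants are
skipped entirely (a truncated peptide cannot be distinguished from one
ending by a missed-cleavage limit); stop-loss variants read through the
original stop for up to 20 extra residues, each requiring read depth
greater than 3 at the translated positions, stopping early at a new
stop codon.  Mutated proteins are digested in silico with trypsin
(cleave after K/R, not before P), emitting peptides that span the
variant with at most three missed cleavages on each side (five on the
N-terminal side for stop-loss products) and at least eight residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

STOP_CODONS = {"TAA", "TAG", "TGA"}
MIN_PEPTIDE_LENGTH = 8
MAX_STOP_LOSS_EXTENSION = 20
MIN_READ_DEPTH = 3


@dataclass
class TranscriptModel:
    """Coding model of one expressed transcript.

    ``cds`` includes the stop codon (length divisible by 3);
    ``three_prime`` is downstream sequence available for stop-loss
    read-through, with per-nucleotide ``depth_three_prime`` read depths.
    """

    id: str
    cds: str
    fpkm: float = 1.0
    three_prime: str = ""
    depth_three_prime: np.ndarray | list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        self.three_prime = self.three_prime.upper()
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.id}: coding length {len(self.cds)} not divisible by 3")
        if self.cds[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.id}: coding sequence must end in a stop codon")
        self.depth_three_prime = np.asarray(self.depth_three_prime, dtype=int)
        if (self.depth_three_prime < 0).any():
            raise ValueError("read depths must be non-negative")
        if len(self.depth_three_prime) != len(self.three_prime):
            raise ValueError(f"{self.id}: depth vector must match three_prime length")


@dataclass
class VariantCall:
    """One SNV or small indel on a transcript's coding sequence (0-based)."""

    transcript_id: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")

    @property
    def var_class(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        if len(self.alt) > len(self.ref):
            return "insertion"
        return "deletion"


@dataclass
class VariantProtein:
    """A mutated translation product with its variant residue span."""

    transcript_id: str
    sequence: str
    description: str
    var_start: int
    var_end: int
    stop_loss: bool = False


def _translate(nt: str) -> str:
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def translate_with_variants(
    transcript: TranscriptModel, variants: list[VariantCall]
) -> list[VariantProtein]:
    """Apply each variant to the coding sequence and translate.

    Each variant is applied independently.  A variant creating a stop
    before the original terminal codon yields no product; a variant
    destroying the stop triggers depth-gated read-through into the
    three-prime sequence.
    """
    products = []
    for var in variants:
        if var.transcript_id != transcript.id:
            continue
        if not 0 <= var.pos < len(transcript.cds) or \
                var.pos + len(var.ref) > len(transcript.cds):
            raise ValueError(
                f"variant at {var.pos} out of range for {transcript.id} "
                f"(length {len(transcript.cds)})"
            )
        if transcript.cds[var.pos: var.pos + len(var.ref)] != var.ref:
            raise ValueError(
                f"ref allele mismatch at {transcript.id}:{var.pos} "
                f"(expected {transcript.cds[var.pos: var.pos + len(var.ref)]!r})"
            )
        mutated = (
            transcript.cds[: var.pos] + var.alt
            + transcript.cds[var.pos + len(var.ref):]
        )
        prot = _translate(mutated)
        n_codons = len(mutated) // 3
        stop_at = prot.find("*")
        desc = f"{var.var_class}:{var.pos}{var.ref}>{var.alt}"
        if stop_at != -1 and stop_at < n_codons - 1:
            # premature stop: stop gain, no record
            continue
        if stop_at == n_codons - 1:
            sequence = prot[:stop_at]
            stop_loss = False
        else:
            # original stop destroyed: depth-gated read-through
            leftover = mutated[n_codons * 3:]
            sequence = prot
            extension, new_stop = _extend_read_through(transcript, leftover)
            sequence += extension
            stop_loss = True
        if not sequence:
            continue
        var_start = var.pos // 3
        frameshift = (len(var.ref) - len(var.alt)) % 3 != 0
        if stop_loss or frameshift:
            var_end = len(sequence) - 1
        else:
            var_end = min(
                var_start + max(len(var.ref), len(var.alt)) // 3,
                len(sequence) - 1,
            )
        products.append(
            VariantProtein(
                transcript_id=transcript.id, sequence=sequence,
                description=desc, var_start=var_start,
                var_end=max(var_end, var_start), stop_loss=stop_loss,
            )
        )
    return products


def _extend_read_through(
    transcript: TranscriptModel, leftover: str
) -> tuple[str, bool]:
    """Translate past a lost stop codon under the depth rule.

    ``leftover`` nucleotides from the (possibly shifted) coding sequence
    are assumed covered; every codon drawing on three-prime positions
    requires depth > 3 at each of them.  At most 20 residues are added;
    a new stop codon ends the extension.
    """
    big = np.full(len(leftover), MIN_READ_DEPTH + 1_000_000, dtype=int)
    nt = leftover + transcript.three_prime
    depth = np.concatenate([big, transcript.depth_three_prime])
    residues = []
    for i in range(0, len(nt) - 2, 3):
        if len(residues) >= MAX_STOP_LOSS_EXTENSION:
            break
        codon = nt[i: i + 3]
        if (depth[i: i + 3] <= MIN_READ_DEPTH).any():
            break
        if codon in STOP_CODONS:
            return "".join(residues), True
        residues.append(str(Seq(codon).translate()))
    return "".join(residues), False


def _cleavage_sites(seq: str) -> list[int]:
    """Positions after which trypsin cuts (after K/R, not before P)."""
    return [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]


def digest(
    sequence: str,
    variant_span: tuple[int, int] | None = None,
    min_len: int = MIN_PEPTIDE_LENGTH,
    max_missed: int = 3,
    n_term_extra_missed: int = 5,
    stop_loss: bool = False,
    full: bool = False,
) -> list[tuple[str, int]]:
    """Tryptic in-silico digestion.

    With ``full=True`` every peptide with at most ``max_missed`` total
    internal missed cleavages is emitted.  Otherwise only peptides
    overlapping ``variant_span`` (inclusive residue range) are kept,
    with at most ``max_missed`` missed cleavages on each side of the
    span — ``n_term_extra_missed`` on the N-terminal side for stop-loss
    products.  Peptides shorter than ``min_len`` are discarded.
    Returns (peptide, start-position) pairs sorted by position then
    length.
    """
    if not sequence:
        return []
    sites = _cleavage_sites(sequence)
    bounds = [0] + sites + [len(sequence)]
    out = []
    left_limit = n_term_extra_missed if stop_loss else max_missed
    for i in range(len(bounds) - 1):
        for j in range(i + 1, len(bounds)):
            start, end = bounds[i], bounds[j]
            internal = [s for s in sites if start < s < end]
            if full:
                if len(internal) > max_missed:
                    break
            else:
                if variant_span is None:
                    raise ValueError("variant_span required unless full=True")
                vs, ve = variant_span
                if not (start <= ve and end > vs):
                    continue
                left = sum(1 for s in internal if s <= vs)
                right = sum(1 for s in internal if s > ve)
                if left > left_limit or right > max_missed:
                    continue
            if end - start >= min_len:
                out.append((sequence[start:end], start))
    return sorted(set(out), key=lambda t: (t[1], len(t[0])))


def build_variant_fasta(
    transcripts: list[TranscriptModel],
    variants: list[VariantCall],
    path=None,
    min_len: int = MIN_PEPTIDE_LENGTH,
    max_missed: int = 3,
    n_term_extra_missed: int = 5,
    fpkm_min: float = 1.0,
) -> list[tuple[str, str]]:
    """Build the deduplicated variant-peptide database.

    Only transcripts with FPKM above ``fpkm_min`` contribute.  Returns
    (header, peptide) pairs in deterministic order and, when ``path``
    is given, writes them as FASTA.
    """
    by_tid = {t.id: t for t in transcripts}
    records: dict[str, str] = {}
    for tid in sorted(by_tid):
        t = by_tid[tid]
        if t.fpkm <= fpkm_min:
            continue
        for prod in translate_with_variants(t, [v for v in variants if v.transcript_id == tid]):
            for pep, start in digest(
                prod.sequence,
                variant_span=(prod.var_start, prod.var_end),
                min_len=min_len, max_missed=max_missed,
                n_term_extra_missed=n_term_extra_missed,
                stop_loss=prod.stop_loss,
            ):
                if pep not in records:
                    records[pep] = f"{tid}|{prod.description}|pos{start}"
    out = sorted(((h, p) for p, h in records.items()))
    if path is not None:
        with open(path, "w") as fh:
            for header, pep in out:
                fh.write(f">{header}\n{pep}\n")
    return out


def jaccard(set_a, set_b) -> float:
    """Jaccard coefficient |A n B| / |A u B| (NaN when both empty)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return float("nan")
    return len(a & b) / len(union)


def mutation_distance_matrix(mutation_sets: dict[str, set]) -> pd.DataFrame:
    """Sample x sample 1 - Jaccard distances over mutation sets.

    Pairs of samples with both sets empty get distance 1 by convention.
    """
    names = sorted(mutation_sets)
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            jc = jaccard(mutation_sets[names[i]], mutation_sets[names[j]])
            d[i, j] = d[j, i] = 1.0 if np.isnan(jc) else 1.0 - jc
    return pd.DataFrame(d, index=names, columns=names)
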