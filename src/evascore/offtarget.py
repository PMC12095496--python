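"""Off-target site enumeration on small genomes.

Scans both strands of a genome for candidate protospacers: a 20-mer
followed by a PAM matching one of the allowed patterns (default NGG and
NAG, the CRISPOR search convention), with at most ``max_mismatches``
substitutions relative to the query spacer. Intended for targeted loci and
toy genomes, not chromosome-scale scans.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

from .guides import GuideRecord, reverse_complement, validate_spacer
from .specificity import mit_aggregate_score, mit_site_score

DEFAULT_PAM_PATTERNS = ("NGG", "NAG")
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class OffTargetSite:
    """One genomic site matching the spacer up to ``max_mismatches``.

    ``start``/``end`` cover the 20-nt protospacer, 0-based half-open on the
    forward strand; ``sequence`` is protospacer + PAM read 5'->3' on
    ``strand``. Mismatch positions are 1-based, 1 = PAM-distal, strictly
    increasing.
    """

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    mismatch_positions: tuple[int, ...]

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


def _pam_matches(pam: str, pattern: str) -> bool:
    return all(base in _IUPAC[sym] for base, sym in zip(pam, pattern))


def load_genome(genome) -> dict[str, str]:
    """Accept a FASTA path, a pyfaidx.Fasta, or a chrom->sequence mapping."""
    if isinstance(genome, Mapping):
        return {str(k): str(v).upper() for k, v in genome.items()}
    if isinstance(genome, (str, os.PathLike)):
        if not os.path.exists(genome):
            raise FileNotFoundError(f"genome FASTA not found: {genome}")
        from Bio import SeqIO

        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")}
    # pyfaidx.Fasta or similar
    return {name: str(genome[name][:]).upper() for name in genome.keys()}


def _scan_strand(spacer, chrom, seq, strand, chrom_len, max_mismatches, pam_patterns):
    sites = []
    n = len(seq)
    for i in range(n - 23 + 1):
        pam = seq[i + 20 : i + 23]
        if not any(_pam_matches(pam, p) for p in pam_patterns):
            continue
        proto = seq[i : i + 20]
        mismatches = tuple(
            j + 1 for j in range(20) if proto[j] != spacer[j]
        )
        if len(mismatches) > max_mismatches:
            continue
        if strand == "+":
            start = i
        else:
            # i is an index into the reverse-complemented sequence
            start = chrom_len - (i + 20)
        sites.append(
            OffTargetSite(
                chrom=chrom,
                start=start,
                end=start + 20,
                strand=strand,
                sequence=proto + pam,
                mismatch_positions=mismatches,
            )
        )
    return sites


def enumerate_offtargets(
    guide: GuideRecord,
    genome,
    max_mismatches: int = 4,
    pam_patterns: tuple[str, ...] = DEFAULT_PAM_PATTERNS,
) -> list[OffTargetSite]:
    """All candidate sites on both strands, the on-target locus excluded.

    The on-target site is identified by coordinates when the guide carries
    them; otherwise the single best perfect match is NOT removed and the
    caller is responsible for excluding it (a perfect-match site at an
    unknown locus is indistinguishable from a perfect off-target).
    """
    if max_mismatches > 4:
        raise ValueError("max_mismatches must be ≤ 4")
    spacer = validate_spacer(guide.spacer)
    chroms = load_genome(genome)
    if genome is not None and isinstance(genome, (str, os.PathLike)) and not chroms:
        raise ValueError(f"genome {genome!r} contains no sequences")
    sites: list[OffTargetSite] = []
    for chrom, seq in chroms.items():
        sites.extend(
            _scan_strand(spacer, chrom, seq, "+", len(seq), max_mismatches, pam_patterns)
        )
        sites.extend(
            _scan_strand(
                spacer,
                chrom,
                reverse_complement(seq),
                "-",
                len(seq),
                max_mismatches,
                pam_patterns,
            )
        )
    if guide.chrom is not None:
        sites = [
            s
            for s in sites
            if not (
                s.chrom == guide.chrom
                and s.start == guide.start
                and s.strand == (guide.strand or "+")
            )
        ]
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def guide_mit_score(guide: GuideRecord, genome, **kwargs) -> float:
    """Aggregate MIT specificity of a guide against a genome."""
    sites = enumerate_offtargets(guide, genome, **kwargs)
    return mit_aggregate_score(mit_site_score(s.mismatch_positions) for s in sites)
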