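"""Nucleotide alignments and compressed site-pattern representation.

``PatternAlignment`` stores the distinct site columns with multiplicities
plus an invertible site->pattern map, and carries per-site (gene, codon
position) labels so partition schemes can be derived from it.  Gaps and N
are treated as fully ambiguous states (marginalized in the likelihood).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = ["PatternAlignment", "read_fasta", "read_phylip", "read_alignment",
           "write_fasta", "write_phylip"]

_VALID = set(b"ACGTN-?")
_CODE: Dict[int, int] = {ord("A"): 0, ord("C"): 1, ord("G"): 2, ord("T"): 3}
AMBIGUOUS = 4


class PatternAlignment:
    """A compressed alignment: distinct columns, weights, and site labels."""

    def __init__(self, taxa: Sequence[str], patterns: np.ndarray,
                 weights: np.ndarray, site_to_pattern: np.ndarray,
                 gene_ids: Optional[Sequence[str]] = None,
                 codon_positions: Optional[np.ndarray] = None):
        self.taxa = list(taxa)
        self.patterns = patterns  # (n_taxa, n_patterns) of single bytes
        self.weights = np.asarray(weights, dtype=np.int64)
        self.site_to_pattern = np.asarray(site_to_pattern, dtype=np.int64)
        n = self.total_length
        self.gene_ids = list(gene_ids) if gene_ids is not None else ["gene1"] * n
        if codon_positions is None:
            codon_positions = np.zeros(n, dtype=np.int8)
        self.codon_positions = np.asarray(codon_positions, dtype=np.int8)
        self._validate()

    def _validate(self):
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError("duplicate taxon labels")
        if self.patterns.shape[0] != len(self.taxa):
            raise ValueError("pattern matrix row count != number of taxa")
        if int(self.weights.sum()) != self.total_length:
            raise ValueError("pattern weights do not conserve total length")
        if len(self.gene_ids) != self.total_length:
            raise ValueError("gene label vector length mismatch")
        if self.codon_positions.shape != (self.total_length,):
            raise ValueError("codon position vector length mismatch")

    # -- construction -------------------------------------------------

    @classmethod
    def from_sequences(cls, taxa: Sequence[str], sequences: Sequence[str],
                       gene_ids: Optional[Sequence[str]] = None,
                       codon_positions: Optional[np.ndarray] = None
                       ) -> "PatternAlignment":
        taxa = list(taxa)
        if not taxa:
            raise ValueError("empty alignment")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: unequal sequence lengths")
        (n_sites,) = lengths
        if n_sites == 0:
            raise ValueError("empty alignment: zero sites")
        mat = np.frombuffer("".join(s.upper() for s in sequences).encode("ascii"),
                            dtype="S1").reshape(len(taxa), n_sites)
        bad = set(mat.tobytes()) - _VALID
        if bad:
            raise ValueError(f"invalid characters in alignment: {sorted(chr(b) for b in bad)}")
        patterns, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True)
        return cls(taxa, np.ascontiguousarray(patterns), counts, inverse,
                   gene_ids=gene_ids, codon_positions=codon_positions)

    # -- basic properties ---------------------------------------------

    @property
    def total_length(self) -> int:
        return int(self.site_to_pattern.shape[0])

    @property
    def n_patterns(self) -> int:
        return int(self.patterns.shape[1])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def codes(self) -> np.ndarray:
        """(n_taxa, n_patterns) int8 codes: A=0 C=1 G=2 T=3, ambiguous=4."""
        raw = self.patterns.view(np.uint8)
        out = np.full(raw.shape, AMBIGUOUS, dtype=np.int8)
        for byte, code in _CODE.items():
            out[raw == byte] = code
        return out

    def to_matrix(self) -> List[str]:
        """Decompress back to per-taxon sequence strings (original order)."""
        full = self.patterns[:, self.site_to_pattern]
        return [full[i].tobytes().decode("ascii") for i in range(self.n_taxa)]

    # -- derived views ------------------------------------------------

    def subset_sites(self, site_indices) -> "PatternAlignment":
        """New PatternAlignment restricted to the given original sites."""
        idx = np.asarray(site_indices, dtype=np.int64)
        if idx.size == 0:
            raise ValueError("empty site selection")
        sub = self.patterns[:, self.site_to_pattern[idx]]
        patterns, inverse, counts = np.unique(
            sub, axis=1, return_inverse=True, return_counts=True)
        return PatternAlignment(
            self.taxa, np.ascontiguousarray(patterns), counts, inverse,
            gene_ids=[self.gene_ids[i] for i in idx],
            codon_positions=self.codon_positions[idx])

    def reorder_taxa(self, taxa: Sequence[str]) -> "PatternAlignment":
        if set(taxa) != set(self.taxa):
            raise ValueError("taxon set mismatch")
        order = [self.taxa.index(t) for t in taxa]
        return PatternAlignment(list(taxa), self.patterns[order, :],
                                self.weights, self.site_to_pattern,
                                gene_ids=self.gene_ids,
                                codon_positions=self.codon_positions)

    @classmethod
    def concatenate(cls, parts: Sequence["PatternAlignment"]) -> "PatternAlignment":
        """Concatenate gene alignments over a shared taxon set."""
        if not parts:
            raise ValueError("nothing to concatenate")
        taxa = parts[0].taxa
        seqs = ["" for _ in taxa]
        genes: List[str] = []
        pos: List[np.ndarray] = []
        for p in parts:
            if set(p.taxa) != set(taxa):
                raise ValueError("taxon set mismatch between genes")
            p = p.reorder_taxa(taxa)
            for i, s in enumerate(p.to_matrix()):
                seqs[i] += s
            genes.extend(p.gene_ids)
            pos.append(p.codon_positions)
        return cls.from_sequences(taxa, seqs, gene_ids=genes,
                                  codon_positions=np.concatenate(pos))

    # -- summaries ----------------------------------------------------

    def empirical_frequencies(self) -> np.ndarray:
        """Observed ACGT frequencies over non-ambiguous characters."""
        codes = self.codes()
        counts = np.zeros(4)
        for s in range(4):
            counts[s] = float(((codes == s) * self.weights[None, :]).sum())
        if counts.sum() == 0:
            raise ValueError("alignment contains no unambiguous characters")
        f = counts / counts.sum()
        # keep strictly positive frequencies for likelihood computations
        f = np.maximum(f, 1e-6)
        return f / f.sum()

    def gc_content(self) -> float:
        """(G+C)/(A+C+G+T) over non-ambiguous characters."""
        codes = self.codes()
        w = self.weights[None, :]
        acgt = float(((codes < 4) * w).sum())
        gc = float((((codes == 1) | (codes == 2)) * w).sum())
        if acgt == 0:
            raise ValueError("alignment contains no unambiguous characters")
        return gc / acgt


def compress_patterns(taxa: Sequence[str], sequences: Sequence[str],
                      **kwargs) -> PatternAlignment:
    """Compress a labeled sequence matrix into site patterns."""
    return PatternAlignment.from_sequences(taxa, sequences, **kwargs)


# ---------------------------------------------------------------------
# File formats


def read_fasta(path) -> PatternAlignment:
    taxa, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        seqs.append(str(rec.seq))
    return PatternAlignment.from_sequences(taxa, seqs)


def read_phylip(path) -> PatternAlignment:
    """Relaxed sequential or interleaved PHYLIP with whitespace-set names."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty phylip file")
    header = lines[0].split()
    if len(header) < 2:
        raise ValueError("phylip header must contain n_taxa and n_sites")
    n_taxa, n_sites = int(header[0]), int(header[1])
    taxa: List[str] = []
    seqs: List[str] = []
    body = [ln for ln in lines[1:] if ln.strip()]
    for ln in body[:n_taxa]:
        parts = ln.split(None, 1)
        if len(parts) == 1:
            raise ValueError(f"phylip line without sequence data: {ln!r}")
        taxa.append(parts[0])
        seqs.append(parts[1].replace(" ", ""))
    if len(taxa) < n_taxa:
        raise ValueError("fewer taxa than declared in phylip header")
    # continuation lines (interleaved format)
    extra = body[n_taxa:]
    for j, ln in enumerate(extra):
        seqs[j % n_taxa] += ln.replace(" ", "")
    if any(len(s) != n_sites for s in seqs):
        raise ValueError("phylip sequence length disagrees with header")
    return PatternAlignment.from_sequences(taxa, seqs)


def read_alignment(path) -> PatternAlignment:
    """Sniff FASTA vs PHYLIP from the first non-blank character."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line.lstrip()[0]
                break
        else:
            raise ValueError("empty alignment file")
    return read_fasta(path) if first == ">" else read_phylip(path)


def write_fasta(path, aln: PatternAlignment, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(aln.taxa, aln.to_matrix()):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_phylip(path, aln: PatternAlignment) -> None:
    seqs = aln.to_matrix()
    with open(path, "w") as fh:
        fh.write(f" {aln.n_taxa} {aln.total_length}\n")
        for name, seq in zip(aln.taxa, seqs):
            fh.write(f"{name}  {seq}\n")
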