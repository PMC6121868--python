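"""Coding-effect classification under the vertebrate mitochondrial code.

Effects are classified by reconstructing the affected codon from a
background (ancestral) sequence, substituting the derived group state, and
translating both codons with NCBI translation table 2 (AGA/AGG = Stop,
ATA = Met, TGA = Trp).  Reverse-strand genes are complemented before
framing.  Changes are reported in the field's usual shorthand: the
nucleotide change counted 1-based from the first base of the annotated CDS
(e.g. G457A) and the amino-acid change as X###Y (e.g. A157T).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .alignment import AlignedDataset, DETERMINED

_TABLE2 = CodonTable.unambiguous_dna_by_id[2]
#: codon -> amino acid (one letter, '*' for stop) under the vertebrate
#: mitochondrial code
VERTEBRATE_MITO_CODE: dict[str, str] = {
    **_TABLE2.forward_table,
    **{c: "*" for c in _TABLE2.stop_codons},
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Feature:
    """One annotated feature; interval stored 0-based half-open."""

    name: str
    start: int
    end: int
    strand: str  # '+' or '-'
    feature_class: str  # CDS | tRNA | rRNA | noncoding
    frame: int = 0  # bases to skip at the gene's 5' end before codon 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r} for {self.name}")
        if self.feature_class not in ("CDS", "tRNA", "rRNA", "noncoding"):
            raise AnnotationError(f"bad feature class {self.feature_class!r}")
        if self.start < 0 or self.end <= self.start:
            raise AnnotationError(f"bad interval for {self.name}")
        if self.frame not in (0, 1, 2):
            raise AnnotationError(f"bad frame offset for {self.name}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAnnotation:
    """The gene layout used for coding-effect classification."""

    features: tuple[Feature, ...]
    alignment_length: int | None = None

    def __post_init__(self) -> None:
        for f in self.features:
            if f.feature_class == "CDS" and (len(f) - f.frame) % 3 != 0:
                raise AnnotationError(
                    f"CDS {f.name} length {len(f)} minus frame {f.frame} "
                    "is not divisible by 3"
                )
            if self.alignment_length is not None and f.end > self.alignment_length:
                raise AnnotationError(f"feature {f.name} exceeds the alignment")

    def features_at(self, site: int) -> list[Feature]:
        return [f for f in self.features if f.start <= site < f.end]

    @classmethod
    def from_tsv(cls, path, alignment_length=None) -> "GeneAnnotation":
        """Read a TSV (name, start, end, strand, class, frame); coordinates
        1-based inclusive as in every user-facing interface."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        feats = tuple(
            Feature(
                name=str(r["name"]),
                start=int(r["start"]) - 1,
                end=int(r["end"]),
                strand=str(r["strand"]),
                feature_class=str(r["class"]),
                frame=int(r.get("frame", 0)) if "frame" in df.columns else 0,
            )
            for _, r in df.iterrows()
        )
        return cls(features=feats, alignment_length=alignment_length)


@dataclass(frozen=True)
class EffectRecord:
    """Classified effect of one substitution in one feature."""

    feature: str | None
    effect_class: str  # synonymous | nonsynonymous | tRNA | rRNA | noncoding
    nt_change: str | None = None  # e.g. "G457A", gene-relative, gene strand
    codon_change: str | None = None  # e.g. "GCA>ACA"
    aa_change: str | None = None  # e.g. "A157T"; stop as '*'
    codon_number: int | None = None


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def consensus_sequence(ds: AlignedDataset, sample_ids) -> str:
    """Site-wise majority consensus over the given samples (N where none
    determined; ties toward the alphabetically first base)."""
    from collections import Counter

    seqs = [ds.sequence(s) for s in sorted(sample_ids)]
    out = []
    for i in range(ds.length):
        states = [s[i] for s in seqs if s[i] in DETERMINED]
        if not states:
            out.append("N")
        else:
            counts = Counter(states)
            top = max(counts.values())
            out.append(sorted(st for st, c in counts.items() if c == top)[0])
    return "".join(out)


def classify_coding_effect(
    site: int,
    group_state: str,
    other_state: str,
    ann: GeneAnnotation,
    background: str,
) -> list[EffectRecord]:
    """Classify the coding effect of a ``other_state -> group_state`` change.

    ``site`` is the 0-based alignment position; ``background`` is the
    ancestral sequence context (typically the non-group consensus) from
    which codons are reconstructed.  One record is returned per feature
    covering the site (overlapping CDS yield one record each); a site in no
    feature yields a single noncoding record.
    """
    if group_state not in DETERMINED or other_state not in DETERMINED:
        raise AnnotationError("states must be determined bases (A/C/G/T)")
    feats = ann.features_at(site)
    if not feats:
        return [EffectRecord(feature=None, effect_class="noncoding")]
    records = []
    for f in feats:
        if f.feature_class in ("tRNA", "rRNA", "noncoding"):
            records.append(EffectRecord(feature=f.name, effect_class=f.feature_class))
            continue
        # CDS: gene-strand coordinates
        if f.strand == "+":
            pos_in_gene = site - f.start  # 0-based from the first CDS base
            anc_base, new_base = other_state, group_state
        else:
            pos_in_gene = (f.end - 1) - site
            anc_base = _COMPLEMENT[other_state]
            new_base = _COMPLEMENT[group_state]
        nt_change = f"{anc_base}{pos_in_gene + 1}{new_base}"
        pos_in_frame = pos_in_gene - f.frame
        if pos_in_frame < 0:
            # upstream of the reading frame within the feature
            records.append(EffectRecord(feature=f.name, effect_class="noncoding",
                                        nt_change=nt_change))
            continue
        codon_idx, codon_pos = divmod(pos_in_frame, 3)
        # alignment coordinates of the codon's three gene-strand bases
        if f.strand == "+":
            c0 = f.start + f.frame + 3 * codon_idx
            codon_sites = [c0, c0 + 1, c0 + 2]
            codon = [background[s] for s in codon_sites]
        else:
            c0 = (f.end - 1) - f.frame - 3 * codon_idx
            codon_sites = [c0, c0 - 1, c0 - 2]
            codon = [_COMPLEMENT.get(background[s], "N") for s in codon_sites]
        codon[codon_pos] = anc_base
        anc_codon = "".join(codon)
        new_codon = anc_codon[:codon_pos] + new_base + anc_codon[codon_pos + 1:]
        if any(b not in DETERMINED for b in anc_codon):
            raise AnnotationError(
                f"codon context around site {site + 1} is undetermined in the "
                "background sequence"
            )
        aa_anc = VERTEBRATE_MITO_CODE[anc_codon]
        aa_new = VERTEBRATE_MITO_CODE[new_codon]
        effect = "synonymous" if aa_anc == aa_new else "nonsynonymous"
        records.append(
            EffectRecord(
                feature=f.name,
                effect_class=effect,
                nt_change=nt_change,
                codon_change=f"{anc_codon}>{new_codon}",
                aa_change=f"{aa_anc}{codon_idx + 1}{aa_new}",
                codon_number=codon_idx + 1,
            )
        )
    return records
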