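"""Protein-level consequence calling for coding InDels.

A genomic InDel is mapped into a transcript's spliced coding sequence,
the mutant CDS is constructed (honouring the VCF anchor-base convention),
both alleles are translated, and the call is classified:

* frameshift       - allele length difference not a multiple of 3
* inframe_deletion / inframe_insertion - multiple-of-3 length change
* stop_gained      - in-frame change creating an earlier stop
* stop_lost        - translation runs through the end of the mutant CDS
* synonymous_boundary - protein unchanged
* noncoding        - variant outside the CDS

The truncation fraction 1 - len(alt protein)/len(ref protein) (stop
codons excluded) and any annotated protein domains extending beyond the
mutant protein's last residue are reported, flagging candidate
loss-of-function alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "ConsequenceCall",
    "map_to_cds",
    "apply_indel",
    "translate",
    "classify",
    "load_gene_models",
]

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ConsequenceError(ValueError):
    """Raised on unmappable or unsupported variant/gene combinations."""


class ExonBoundaryError(ConsequenceError):
    """InDel spans a splice boundary; effect on the mature transcript is undefined."""


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A coding transcript: ordered genomic CDS exons plus the spliced CDS."""

    gene_id: str
    chrom: str
    strand: str
    cds_exons: list[tuple[int, int]]  # 1-based inclusive, ascending genomic order
    cds_sequence: str  # transcript orientation, 5'->3'

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConsequenceError(f"strand must be + or -, got {self.strand!r}")
        self.cds_sequence = self.cds_sequence.upper()
        exon_len = sum(e - s + 1 for s, e in self.cds_exons)
        if exon_len != len(self.cds_sequence):
            raise ConsequenceError(
                f"{self.gene_id}: exon span {exon_len} != CDS length {len(self.cds_sequence)}"
            )

    def validate(self) -> None:
        """Check the CDS is a complete ORF (starts ATG, ends with a stop)."""
        seq = self.cds_sequence
        if len(seq) % 3 != 0:
            raise ConsequenceError(f"{self.gene_id}: CDS length not a multiple of 3")
        if not seq.startswith("ATG"):
            raise ConsequenceError(f"{self.gene_id}: CDS does not start with ATG")
        if seq[-3:] not in _STOPS:
            raise ConsequenceError(f"{self.gene_id}: CDS does not end in a stop codon")

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_exons[0][0], self.cds_exons[-1][1]


@dataclass
class ConsequenceCall:
    variant_id: str
    gene_id: str
    consequence_class: str
    ref_protein: str
    alt_protein: str
    truncation_fraction: float
    lost_domains: list[tuple[str, str]] = field(default_factory=list)  # (label, full|partial)
    deleted_reference: str = ""  # deleted reference bases, verbatim
    notes: list[str] = field(default_factory=list)


def map_to_cds(gene: GeneModel, pos: int, allele_len: int = 1):
    """Map a genomic position (plus ``allele_len - 1`` following bases) into CDS coordinates.

    Returns the 1-based CDS offset of the *first transcript base* of the
    span, or the string ``"noncoding"`` when the span lies entirely outside
    the CDS.  A span that crosses an exon boundary (or only partially
    overlaps the CDS) raises :class:`ExonBoundaryError`.
    """
    lo, hi = pos, pos + allele_len - 1
    containing = None
    overlapping = False
    for s, e in gene.cds_exons:
        if lo >= s and hi <= e:
            containing = (s, e)
            break
        if hi >= s and lo <= e:
            overlapping = True
    if containing is None:
        if overlapping:
            raise ExonBoundaryError(
                f"{gene.gene_id}: span {gene.chrom}:{lo}-{hi} crosses an exon boundary"
            )
        return "noncoding"

    if gene.strand == "+":
        offset = 0
        for s, e in gene.cds_exons:
            if (s, e) == containing:
                return offset + (lo - s) + 1
            offset += e - s + 1
    else:
        offset = 0
        for s, e in reversed(gene.cds_exons):
            if (s, e) == containing:
                # on the minus strand the transcript reads genomic high -> low
                return offset + (e - hi) + 1
            offset += e - s + 1
    raise AssertionError("unreachable")


def apply_indel(cds: str, cds_pos: int, ref: str, alt: str) -> str:
    """Replace ``ref`` by ``alt`` at 1-based ``cds_pos`` of a transcript-oriented CDS.

    ``ref``/``alt`` follow the VCF anchored convention (shared leading base
    kept once); both must already be in transcript orientation.
    """
    cds = cds.upper()
    ref = ref.upper()
    alt = alt.upper()
    found = cds[cds_pos - 1 : cds_pos - 1 + len(ref)]
    if found != ref:
        raise ConsequenceError(
            f"reference mismatch at CDS position {cds_pos}: transcript has "
            f"{found!r}, variant claims {ref!r}"
        )
    return cds[: cds_pos - 1] + alt + cds[cds_pos - 1 + len(ref) :]


def translate(cds: str) -> tuple[str, list[str]]:
    """Translate from position 1 with the standard table, stopping at the first stop.

    Returns (protein, notes); a ``stop_lost`` note is attached when no
    in-frame stop is reached before the end of the sequence.  A trailing
    partial codon is ignored.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ConsequenceError("sequence shorter than one codon")
    bad = set(cds) - set("ACGT")
    if bad:
        raise ConsequenceError(f"non-ACGT characters in CDS: {sorted(bad)}")
    trimmed = cds[: len(cds) // 3 * 3]
    aa = str(Seq(trimmed).translate())
    notes: list[str] = []
    stop = aa.find("*")
    if stop == -1:
        notes.append("stop_lost")
        return aa, notes
    return aa[:stop], notes


def classify(gene: GeneModel, variant, domains=None) -> ConsequenceCall:
    """Classify a variant's protein-level effect on one gene model.

    ``variant`` needs chrom/pos/ref/alt attributes (plus-strand genomic,
    VCF anchored).  ``domains`` is an optional iterable of
    (label, start_residue, end_residue) intervals on the reference protein.
    """
    if variant.chrom != gene.chrom:
        raise ConsequenceError(
            f"variant {variant.chrom}:{variant.pos} not on gene chromosome {gene.chrom}"
        )
    ref, alt = variant.ref.upper(), variant.alt.upper()
    vid = f"{variant.chrom}_{variant.pos}"

    ref_protein, _ = translate(gene.cds_sequence)
    mapped = map_to_cds(gene, variant.pos, len(ref))
    if mapped == "noncoding":
        return ConsequenceCall(
            variant_id=vid,
            gene_id=gene.gene_id,
            consequence_class="noncoding",
            ref_protein=ref_protein,
            alt_protein=ref_protein,
            truncation_fraction=0.0,
        )

    if gene.strand == "+":
        t_ref, t_alt, t_pos = ref, alt, mapped
    else:
        t_ref, t_alt, t_pos = _revcomp(ref), _revcomp(alt), mapped

    mutant = apply_indel(gene.cds_sequence, t_pos, t_ref, t_alt)
    alt_protein, alt_notes = translate(mutant)

    diff = len(alt) - len(ref)
    if diff % 3 != 0:
        cls = "frameshift"
    elif "stop_lost" in alt_notes:
        cls = "stop_lost"
    elif alt_protein == ref_protein:
        cls = "synonymous_boundary"
    else:
        expected_len = len(ref_protein) + diff // 3
        if len(alt_protein) < expected_len:
            cls = "stop_gained"
        elif diff < 0:
            cls = "inframe_deletion"
        else:
            cls = "inframe_insertion"

    trunc = 1.0 - len(alt_protein) / len(ref_protein) if ref_protein else 0.0

    lost: list[tuple[str, str]] = []
    if domains:
        alt_len = len(alt_protein)
        for label, d_start, d_end in domains:
            if d_start > alt_len:
                lost.append((str(label), "full"))
            elif d_end > alt_len:
                lost.append((str(label), "partial"))

    deleted = ref[len(alt):] if len(ref) > len(alt) and ref.startswith(alt) else ""
    return ConsequenceCall(
        variant_id=vid,
        gene_id=gene.gene_id,
        consequence_class=cls,
        ref_protein=ref_protein,
        alt_protein=alt_protein,
        truncation_fraction=trunc,
        lost_domains=lost,
        deleted_reference=deleted,
        notes=alt_notes,
    )


def load_gene_models(gff3_path, fasta_path, validate: bool = True) -> list[GeneModel]:
    """Build GeneModels from a GFF3 annotation and its reference FASTA.

    CDS features are grouped by parent transcript (falling back to the gene
    when no mRNA level exists); the spliced CDS is extracted strand-aware
    from the FASTA.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        cds = sorted(
            db.children(gene, featuretype="CDS"), key=lambda f: f.start
        )
        if not cds:
            continue
        if gene.seqid not in fasta:
            raise ConsequenceError(
                f"chromosome {gene.seqid!r} absent from FASTA "
                f"(available: {list(fasta.keys())})"
            )
        exons = [(f.start, f.end) for f in cds]
        parts = [str(fasta[gene.seqid][s - 1 : e]) for s, e in exons]
        seq = "".join(parts)
        if gene.strand == "-":
            seq = _revcomp(seq)
        model = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            cds_exons=exons,
            cds_sequence=seq,
        )
        if validate:
            model.validate()
        models.append(model)
    return models
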