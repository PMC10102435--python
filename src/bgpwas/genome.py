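"""Variant ingestion, dosage encoding, kinship and LOCO principal components.

Genotypes are encoded as alternate-allele dosages in {0, 1, 2}.  Relatedness
uses the VanRaden centered genomic relationship matrix

    K = Z Z' / (2 * sum_j f_j (1 - f_j)),   Z = G - 2f

and population-structure covariates are leave-one-chromosome-out (LOCO)
principal components: the PCs supplied for a variant on chromosome c are
computed from all variants *except* those on c, so the structure covariates
cannot absorb the tested variant's own signal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VariantRecord",
    "KinshipMatrix",
    "LocoPCSet",
    "read_variants",
    "read_samples",
    "is_indel",
    "maf_filter",
    "compute_kinship",
    "loco_pcs",
    "select_window",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class GenomeError(ValueError):
    """Raised on invalid genomic inputs."""


@dataclass
class VariantRecord:
    """A single bi-allelic variant with per-accession alt-allele dosages."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if not (_ALLELE_RE.match(self.ref) and _ALLELE_RE.match(self.alt)):
            raise GenomeError(
                f"non-ACGT alleles at {self.chrom}:{self.pos} ({self.ref}>{self.alt})"
            )
        self.dosage = np.asarray(self.dosage, dtype=float)

    @property
    def id(self) -> str:
        return f"{self.chrom}_{self.pos}"

    @property
    def maf(self) -> float:
        f = float(self.dosage.mean()) / 2.0
        return min(f, 1.0 - f)


@dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix aligned to an accession order."""

    values: np.ndarray
    accession_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise GenomeError("kinship shape must match accession count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise GenomeError("kinship must be symmetric")


@dataclass
class LocoPCSet:
    """Per-chromosome principal-component scores (complement-chromosome PCA)."""

    scores: dict[str, np.ndarray]  # chrom -> N x n_pcs
    explained: dict[str, np.ndarray] = field(default_factory=dict)
    accession_ids: list[str] | None = None


def _parse_region(region: str) -> tuple[str, int, int]:
    m = re.match(r"^(.+):(\d+)-(\d+)$", region)
    if not m:
        raise GenomeError(f"malformed region {region!r}; expected chrom:start-end")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start < 1 or end < start:
        raise GenomeError(f"invalid region bounds in {region!r}")
    return chrom, start, end


def read_samples(vcf_path) -> list[str]:
    """Accession IDs from a VCF header."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    try:
        return list(vcf.samples)
    finally:
        vcf.close()


def read_variants(vcf_path, region: str | None = None):
    """Stream VariantRecords from a VCF (plain or bgzipped).

    Genotypes must be complete (inputs are assumed imputed upstream); a
    missing genotype raises.  Multi-allelic sites are decomposed into one
    record per alternate allele, each dosage counting that allele only.
    ``region`` is "chrom:start-end", 1-based inclusive; a tabix index is
    used when present, otherwise the stream is filtered.
    """
    from cyvcf2 import VCF

    path = str(vcf_path)
    if not Path(path).exists():
        raise GenomeError(f"VCF not found: {path}")
    vcf = VCF(path, gts012=False)
    want = _parse_region(region) if region else None
    indexed = want is not None and (
        Path(path + ".tbi").exists() or Path(path + ".csi").exists()
    )
    try:
        iterator = vcf(region) if indexed else vcf
        for v in iterator:
            if want is not None:
                chrom, start, end = want
                if v.CHROM != chrom or not (start <= v.POS <= end):
                    continue
            gts = v.genotype.array()[:, :2]
            if (gts < 0).any():
                bad = int(np.where((gts < 0).any(axis=1))[0][0])
                raise GenomeError(
                    f"missing genotype at {v.CHROM}:{v.POS} (sample index {bad}); "
                    "inputs must be imputed"
                )
            for k, alt in enumerate(v.ALT, start=1):
                if not _ALLELE_RE.match(alt.upper()) or not _ALLELE_RE.match(v.REF.upper()):
                    continue  # symbolic/star alleles are not modelled
                dosage = (gts == k).sum(axis=1).astype(float)
                yield VariantRecord(
                    chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt, dosage=dosage
                )
    except GenomeError:
        raise
    except Exception as exc:  # pragma: no cover - backend parse failures
        raise GenomeError(f"failed parsing {path}: {exc}") from exc
    finally:
        vcf.close()


def is_indel(v: VariantRecord) -> bool:
    """True iff ref and alt allele lengths differ (insertions and deletions)."""
    return len(v.ref) != len(v.alt)


def maf_filter(variants, min_maf: float = 0.1):
    """Retain variants with minor-allele frequency >= ``min_maf``."""
    return [v for v in variants if v.maf >= min_maf]


def compute_kinship(G, accession_ids: list[str] | None = None) -> KinshipMatrix:
    """VanRaden centered genomic relationship matrix from an N x M dosage matrix."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] < 2:
        raise GenomeError("need an N x M dosage matrix with M >= 2")
    f = G.mean(axis=0) / 2.0
    poly = (f > 0) & (f < 1)
    if not poly.any():
        raise GenomeError("all variants are monomorphic; kinship undefined")
    Z = G[:, poly] - 2.0 * f[poly]
    denom = 2.0 * float(np.sum(f[poly] * (1.0 - f[poly])))
    K = (Z @ Z.T) / denom
    K = 0.5 * (K + K.T)
    ids = accession_ids or [f"acc{i}" for i in range(G.shape[0])]
    return KinshipMatrix(values=K, accession_ids=list(ids))


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector orientation: largest-|loading| entry positive."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        k = int(np.argmax(np.abs(out[:, j])))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def loco_pcs(
    G,
    chrom_labels,
    n_pcs: int = 3,
    accession_ids: list[str] | None = None,
) -> LocoPCSet:
    """Leave-one-chromosome-out principal components.

    For every chromosome c the scores are the top-``n_pcs`` eigenvectors of
    the VanRaden kinship built from all variants *not* on c, scaled by the
    square root of their eigenvalues.  Deterministic up to the fixed sign
    convention.
    """
    G = np.asarray(G, dtype=float)
    labels = np.asarray(chrom_labels)
    if labels.shape[0] != G.shape[1]:
        raise GenomeError("chrom_labels length must equal variant count")
    chroms = sorted(set(labels.tolist()))
    if len(chroms) < 2:
        raise GenomeError("LOCO requires at least 2 chromosomes")
    scores: dict[str, np.ndarray] = {}
    explained: dict[str, np.ndarray] = {}
    for c in chroms:
        sub = G[:, labels != c]
        K = compute_kinship(sub).values
        evals, evecs = np.linalg.eigh(K)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        tol = 1e-8 * max(1.0, float(evals[0]))
        informative = int((evals > tol).sum())
        if informative < n_pcs:
            raise GenomeError(
                f"chromosome {c}: complement has only {informative} informative "
                f"dimensions (< {n_pcs})"
            )
        vecs = _fix_signs(evecs[:, :n_pcs])
        scores[c] = vecs * np.sqrt(evals[:n_pcs])
        pos = np.clip(evals, 0.0, None)
        explained[c] = evals[:n_pcs] / pos.sum()
    return LocoPCSet(scores=scores, explained=explained, accession_ids=accession_ids)


def select_window(variants, gene_interval, flank_bp: int = 100_000):
    """Variants within ``flank_bp`` of a gene interval (chrom, start, end).

    The window is [start - flank, end + flank], 1-based inclusive, clipped
    at position 1.
    """
    if flank_bp < 0:
        raise GenomeError("flank_bp must be >= 0")
    chrom, start, end = gene_interval
    lo = max(1, start - flank_bp)
    hi = end + flank_bp
    return [v for v in variants if v.chrom == chrom and lo <= v.pos <= hi]
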