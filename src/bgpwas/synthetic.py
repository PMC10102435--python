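"""Synthetic genotype-phenome datasets with known causal structure.

The generator draws populations (binomial dosages, optional Balding-
Nichols deme structure), phenomes from the same matrix-normal mixed model
the imputer assumes (Y = S beta + eps with kinship-structured S), injects
dosage-proportional causal effects into chosen traits, applies MCAR or
block missingness with held-out truth, and builds toy coding genes with
labelled candidate InDels.  Writers emit the standard formats the pipeline
reads (VCF, phenotype TSV, GFF3, FASTA) so fixtures exercise the real
parsers end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consequence import GeneModel
from .genome import KinshipMatrix, compute_kinship
from .phenome import TraitMatrix

__all__ = [
    "SimPopulation",
    "SimTruth",
    "simulate_population",
    "simulate_phenome",
    "inject_causal_variant",
    "mask_missing",
    "make_toy_gene",
    "write_vcf",
    "write_phenotypes",
    "write_gff3",
    "write_fasta",
]

_STOPS = ("TAA", "TAG", "TGA")
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


class SyntheticError(ValueError):
    pass


@dataclass
class SimPopulation:
    G: np.ndarray  # N x M dosages
    chrom_labels: np.ndarray  # length M
    positions: np.ndarray  # length M, 1-based
    accession_ids: list[str]
    kinship: KinshipMatrix
    freqs: np.ndarray
    demes: np.ndarray | None = None
    seed: int | None = None


@dataclass
class SimTruth:
    """Ground truth for recovery scoring."""

    causal: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    latents: dict = field(default_factory=dict)
    kinship: np.ndarray | None = None
    missing_mask: np.ndarray | None = None
    held_out: dict[tuple[int, int], float] = field(default_factory=dict)
    seed: int | None = None


def simulate_population(
    n: int,
    n_variants: int,
    n_chrom: int = 2,
    maf_range: tuple[float, float] = (0.1, 0.5),
    block_structure: int | None = None,
    fst: float = 0.2,
    seed: int = 0,
) -> SimPopulation:
    """Binomial(2, f) dosages with optional deme (block) structure.

    With ``block_structure`` demes, per-deme allele frequencies are drawn
    from a Balding-Nichols beta around the ancestral frequency with the
    given ``fst``, inducing genuine kinship blocks.
    """
    if n < 2:
        raise SyntheticError("need at least 2 accessions")
    lo, hi = maf_range
    if not (0.0 < lo < hi <= 0.5):
        raise SyntheticError(f"degenerate maf_range {maf_range}")
    rng = np.random.default_rng(seed)
    f = rng.uniform(lo, hi, size=n_variants)
    if block_structure:
        demes = np.repeat(np.arange(block_structure), -(-n // block_structure))[:n]
        a = f * (1.0 - fst) / fst
        b = (1.0 - f) * (1.0 - fst) / fst
        f_deme = rng.beta(a, b, size=(block_structure, n_variants))
        f_deme = np.clip(f_deme, 0.01, 0.99)
        G = rng.binomial(2, f_deme[demes, :]).astype(float)
    else:
        demes = None
        G = rng.binomial(2, f[None, :].repeat(n, axis=0)).astype(float)
    # chromosomes as contiguous blocks of variants with increasing positions
    per = -(-n_variants // n_chrom)
    chrom_labels = np.array(
        [f"Chr{1 + i // per:02d}" for i in range(n_variants)]
    )
    positions = np.array([100 * ((i % per) + 1) for i in range(n_variants)])
    ids = [f"acc{i:03d}" for i in range(n)]
    K = compute_kinship(G, accession_ids=ids)
    return SimPopulation(
        G=G,
        chrom_labels=chrom_labels,
        positions=positions,
        accession_ids=ids,
        kinship=K,
        freqs=f,
        demes=demes,
        seed=seed,
    )


def simulate_phenome(
    K,
    p: int,
    rank: int = 2,
    tau: float = 1.0,
    noise_cov: np.ndarray | float = 1.0,
    seed: int = 0,
    accession_ids: list[str] | None = None,
    beta: np.ndarray | None = None,
) -> tuple[TraitMatrix, dict]:
    """Forward-simulate the MPMM: Y = S beta + eps.

    S ~ MN(0, K, I_rank), beta entries iid N(0, 1/tau), residual rows iid
    N(0, E) where a scalar ``noise_cov`` c gives E = c^2 I and a p x p
    matrix is used as E directly.  Passing ``beta`` fixes the loading
    matrix instead of drawing it (e.g. the identity for per-trait
    independent genetic effects, giving a diagonal genetic covariance).
    """
    Kv = np.asarray(getattr(K, "values", K), dtype=float)
    N = Kv.shape[0]
    if rank > p:
        raise SyntheticError("rank must not exceed p")
    evals, evecs = np.linalg.eigh(0.5 * (Kv + Kv.T))
    if evals.min() < -1e-8 * max(1.0, evals.max()):
        raise SyntheticError(f"K not PSD (min eigenvalue {evals.min():.3e})")
    Kroot = evecs * np.sqrt(np.clip(evals, 0.0, None))
    rng = np.random.default_rng(seed)
    S = Kroot @ rng.standard_normal((N, rank))
    if beta is None:
        beta = rng.standard_normal((rank, p)) / np.sqrt(tau)
    else:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (rank, p):
            raise SyntheticError(f"beta must be rank x p = {(rank, p)}, got {beta.shape}")
    if np.isscalar(noise_cov):
        E = float(noise_cov) ** 2 * np.eye(p)
    else:
        E = np.asarray(noise_cov, dtype=float)
        ev = np.linalg.eigvalsh(0.5 * (E + E.T))
        if ev.min() < -1e-8 * max(1.0, ev.max()):
            raise SyntheticError("noise_cov not PSD")
    eps = rng.standard_normal((N, p)) @ np.linalg.cholesky(
        E + 1e-12 * np.eye(p)
    ).T
    Y = S @ beta + eps
    ids = accession_ids or getattr(K, "accession_ids", None) or [
        f"acc{i:03d}" for i in range(N)
    ]
    tm = TraitMatrix(
        values=Y,
        mask=np.ones_like(Y, dtype=bool),
        accession_ids=list(ids),
        trait_names=[f"trait{j:03d}" for j in range(p)],
    )
    latents = {"S": S, "beta": beta, "E": E, "seed": seed}
    return tm, latents


def inject_causal_variant(
    Y: TraitMatrix,
    dosage: np.ndarray,
    causal_traits: list[int],
    effect_sizes: list[float],
    variant_id: str = "causal",
    truth: SimTruth | None = None,
) -> tuple[TraitMatrix, SimTruth]:
    """Add dosage-proportional shifts to chosen traits; record the truth."""
    if len(causal_traits) != len(effect_sizes):
        raise SyntheticError("causal_traits and effect_sizes lengths differ")
    if len(set(causal_traits)) != len(causal_traits):
        raise SyntheticError("causal traits must be distinct")
    dosage = np.asarray(dosage, dtype=float)
    vals = Y.values.copy()
    for t, eff in zip(causal_traits, effect_sizes):
        if not 0 <= t < Y.p:
            raise SyntheticError(f"trait index {t} out of range [0, {Y.p})")
        if not np.isfinite(eff):
            raise SyntheticError("effect sizes must be finite")
        vals[:, t] = vals[:, t] + eff * dosage
    out = TraitMatrix(
        values=vals,
        mask=Y.mask.copy(),
        accession_ids=list(Y.accession_ids),
        trait_names=list(Y.trait_names),
        standardization=Y.standardization,
    )
    truth = truth or SimTruth()
    truth.causal[variant_id] = list(zip(causal_traits, [float(e) for e in effect_sizes]))
    return out, truth


def mask_missing(
    Y: TraitMatrix,
    per_trait_rates,
    pattern: str = "uniform",
    seed: int = 0,
    n_blocks: int = 4,
) -> tuple[TraitMatrix, SimTruth]:
    """Hide entries MCAR (uniform) or in accession x trait blocks.

    Returns the masked matrix and a SimTruth whose ``held_out`` maps
    (row, col) -> true value for recovery scoring.
    """
    rates = np.broadcast_to(np.asarray(per_trait_rates, dtype=float), (Y.p,))
    if rates.min() < 0 or rates.max() > 0.9:
        raise SyntheticError("missing rates must lie in [0, 0.9]")
    rng = np.random.default_rng(seed)
    mask = Y.mask.copy()
    if pattern == "uniform":
        drop = rng.random((Y.n, Y.p)) < rates[None, :]
        mask &= ~drop
    elif pattern == "block":
        for j in range(Y.p):
            target = int(round(rates[j] * Y.n))
            placed = 0
            for _ in range(n_blocks):
                if placed >= target:
                    break
                size = max(1, target // n_blocks)
                start = int(rng.integers(0, max(1, Y.n - size)))
                mask[start : start + size, j] = False
                placed += size
    else:
        raise SyntheticError(f"unknown pattern {pattern!r}")
    fully_masked = [Y.trait_names[j] for j in range(Y.p) if not mask[:, j].any()]
    if fully_masked:
        raise SyntheticError(f"traits fully masked: {fully_masked}")
    held = {
        (int(i), int(j)): float(Y.values[i, j])
        for i, j in zip(*np.where(Y.mask & ~mask))
    }
    out = TraitMatrix(
        values=np.where(mask, Y.values, np.nan),
        mask=mask,
        accession_ids=list(Y.accession_ids),
        trait_names=list(Y.trait_names),
        standardization=Y.standardization,
    )
    truth = SimTruth(missing_mask=mask, held_out=held, seed=seed)
    return out, truth


def make_toy_gene(
    n_exons: int = 2,
    strand: str = "+",
    n_codons: int = 60,
    intron_len: int = 40,
    offset: int = 200,
    chrom: str = "ChrT",
    seed: int = 0,
):
    """Random valid coding gene embedded in a synthetic chromosome.

    Returns (GeneModel, chromosome sequence, candidates) where candidates
    are dicts with pos/ref/alt (plus-strand genomic, VCF anchored) and an
    ``expected_class`` label: one frameshift deletion, one frameshift
    insertion, one codon-aligned in-frame deletion, and (for multi-exon
    genes) one intronic deletion.
    """
    if n_exons < 1:
        raise SyntheticError("n_exons must be >= 1")
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [
        _SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), size=n_codons - 2)
    ] + [str(rng.choice(_STOPS))]
    cds = "".join(codons)

    # split the CDS across exons (genomic orientation = transcript orientation
    # for +; reversed and complemented for -)
    genomic_cds = cds if strand == "+" else cds.translate(_COMPLEMENT_TT)[::-1]
    L = len(genomic_cds)
    cuts = sorted(rng.choice(np.arange(3, L - 3), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    pieces = []
    prev = 0
    for c in list(cuts) + [L]:
        pieces.append(genomic_cds[prev:c])
        prev = c

    bases = np.array(list("ACGT"))
    seq_parts = ["".join(rng.choice(bases, size=offset))]
    exons = []
    cursor = offset
    for k, piece in enumerate(pieces):
        start = cursor + 1  # 1-based
        exons.append((start, start + len(piece) - 1))
        seq_parts.append(piece)
        cursor += len(piece)
        if k < len(pieces) - 1:
            seq_parts.append("".join(rng.choice(bases, size=intron_len)))
            cursor += intron_len
    seq_parts.append("".join(rng.choice(bases, size=offset)))
    chrom_seq = "".join(seq_parts)

    gene = GeneModel(
        gene_id=f"toygene_{strand}_{seed}",
        chrom=chrom,
        strand=strand,
        cds_exons=exons,
        cds_sequence=cds,
    )
    gene.validate()

    candidates = []

    def anchored_del(pos: int, length: int) -> dict:
        ref = chrom_seq[pos - 1 : pos + length]
        return {"pos": pos, "ref": ref, "alt": ref[0]}

    # frameshift: 1-base deletion in the interior of the widest exon
    widest = max(exons, key=lambda ab: ab[1] - ab[0])
    mid = (widest[0] + widest[1]) // 2
    fs = anchored_del(mid, 1)
    fs["expected_class"] = "frameshift"
    candidates.append(fs)

    # frameshift insertion: +1 base after the same anchor
    ins_base = "ACGT"[int(rng.integers(0, 4))]
    candidates.append(
        {
            "pos": mid,
            "ref": chrom_seq[mid - 1],
            "alt": chrom_seq[mid - 1] + ins_base,
            "expected_class": "frameshift",
        }
    )

    # in-frame: codon-aligned 3-base deletion (remove one complete codon)
    tpos = _codon_aligned_anchor(gene, widest)
    inframe = anchored_del(tpos, 3)
    inframe["expected_class"] = "inframe_deletion"
    candidates.append(inframe)

    if n_exons > 1:
        intron_start = exons[0][1] + 1
        intron_pos = intron_start + intron_len // 2
        nc = anchored_del(intron_pos, 1)
        nc["expected_class"] = "noncoding"
        candidates.append(nc)

    return gene, chrom_seq, candidates


_COMPLEMENT_TT = str.maketrans("ACGT", "TGCA")


def _codon_aligned_anchor(gene: GeneModel, exon: tuple[int, int]) -> int:
    """Genomic position whose following 3 bases delete one full codon.

    The anchor base must sit at a CDS offset divisible by 3 (last base of
    the previous codon, not the first codon or the stop), with the 3
    deleted bases inside the same exon.
    """
    from .consequence import map_to_cds

    s, e = exon
    L = len(gene.cds_sequence)
    for pos in range(s + 1, e - 3):
        res = map_to_cds(gene, pos, 4)
        if not isinstance(res, int):
            continue
        # + strand: deleted transcript offsets are res+1..res+3 (anchor at res);
        # - strand: res is the highest genomic base = first transcript base,
        #   so the deleted offsets are res..res+2 and the anchor sits at res+3.
        first_deleted = res + 1 if gene.strand == "+" else res
        if first_deleted % 3 == 1 and first_deleted >= 4 and first_deleted + 2 <= L - 3:
            return pos
    raise SyntheticError("no codon-aligned anchor found; enlarge the exon")


# ---------------------------------------------------------------------------
# writers: the same plain-text formats the pipeline parsers read


def write_vcf(path, pop: SimPopulation) -> None:
    """Plain-text VCF 4.2 with GT genotypes reconstructed from dosages."""
    chrom_order = list(dict.fromkeys(pop.chrom_labels.tolist()))
    lines = ["##fileformat=VCFv4.2", "##source=bgpwas-synthetic"]
    for c in chrom_order:
        on_c = pop.positions[pop.chrom_labels == c]
        lines.append(f"##contig=<ID={c},length={int(on_c.max()) + 1000}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(pop.accession_ids)
    )
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j in range(pop.G.shape[1]):
        gts = "\t".join(gt_map[int(d)] for d in pop.G[:, j])
        lines.append(
            f"{pop.chrom_labels[j]}\t{int(pop.positions[j])}\t"
            f"{pop.chrom_labels[j]}_{int(pop.positions[j])}\tA\tT\t.\tPASS\t.\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_phenotypes(path, tm: TraitMatrix, sep: str = "\t") -> None:
    """Accession x trait table; empty cells mark missing values."""
    df = tm.to_dataframe()
    df.index.name = "accession"
    df.to_csv(path, sep=sep, na_rep="NA")


def write_gff3(path, gene: GeneModel, chrom_len: int) -> None:
    lines = ["##gff-version 3", f"##sequence-region {gene.chrom} 1 {chrom_len}"]
    g_start, g_end = gene.span
    lines.append(
        f"{gene.chrom}\tsynthetic\tgene\t{g_start}\t{g_end}\t.\t{gene.strand}\t."
        f"\tID={gene.gene_id}"
    )
    mrna_id = f"{gene.gene_id}.1"
    lines.append(
        f"{gene.chrom}\tsynthetic\tmRNA\t{g_start}\t{g_end}\t.\t{gene.strand}\t."
        f"\tID={mrna_id};Parent={gene.gene_id}"
    )
    # GFF3 phase: leading bases to remove to reach the next codon start
    exons = gene.cds_exons if gene.strand == "+" else list(reversed(gene.cds_exons))
    phase = 0
    rows = []
    for s, e in exons:
        rows.append((s, e, phase))
        phase = (3 - ((e - s + 1 - phase) % 3)) % 3
    for s, e, ph in sorted(rows):
        lines.append(
            f"{gene.chrom}\tsynthetic\tCDS\t{s}\t{e}\t.\t{gene.strand}\t{ph}"
            f"\tID=cds_{mrna_id};Parent={mrna_id}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_indel_vcf(path, chrom: str, chrom_len: int, candidates, n_samples: int = 4,
                    dosages: np.ndarray | None = None, sample_ids=None) -> None:
    """VCF holding candidate InDels (for consequence-pipeline fixtures)."""
    ids = sample_ids or [f"acc{i:03d}" for i in range(n_samples)]
    lines = [
        "##fileformat=VCFv4.2",
        "##source=bgpwas-synthetic",
        f"##contig=<ID={chrom},length={chrom_len}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids),
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for k, cand in enumerate(sorted(candidates, key=lambda c: c["pos"])):
        if dosages is not None:
            gts = "\t".join(gt_map[int(d)] for d in dosages[:, k])
        else:
            gts = "\t".join(["0/1"] * len(ids))
        lines.append(
            f"{chrom}\t{cand['pos']}\t{chrom}_{cand['pos']}\t{cand['ref']}\t"
            f"{cand['alt']}\t.\tPASS\t.\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
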