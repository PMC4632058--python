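"""Genotype matrix data model and file I/O.

Genotypes of unphased biallelic diploid SNPs are coded as minor-allele
dosages: 0 = homozygous major, 1 = heterozygous, 2 = homozygous minor.
Missing calls are coded with the sentinel ``MISSING`` (−1), both in memory
and in the plain tab-delimited numeric dialect.

Two on-disk formats are supported:

* VCF 4.x (only the GT field is consumed/produced), through pysam;
* a plain tab-delimited dosage matrix, one row per sample, ``-1`` missing,
  with an optional header row of SNP IDs and an optional leading column of
  sample IDs (auto-detected on read).

Marker order is never interpreted by the imputation algorithms: chromosome
and position labels are carried as opaque annotations only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call, in memory and in numeric files.
MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


class GenotypeFormatError(ValueError):
    """Raised when an input file violates the genotype-matrix contracts."""


@dataclass
class GenotypeMatrix:
    """Samples × SNPs dosage matrix with identifiers and optional coordinates.

    Parameters
    ----------
    dosage
        Integer array of shape ``(n_samples, n_snps)`` with entries in
        ``{0, 1, 2, MISSING}``.
    samples, snps
        Unique identifier lists matching the two axes.
    chrom, pos, ref, alt
        Optional per-SNP annotations (all-or-none for chrom/pos). Positions
        follow the VCF convention (1-based). They are opaque labels: no
        algorithm in this package orders markers by position.
    """

    dosage: np.ndarray
    samples: list[str]
    snps: list[str]
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x snps)")
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosage, (-1, 0, 1, 2))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {int(self.dosage[r, c])} at sample {r}, snp {c}"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample IDs are not unique")
        if len(set(self.snps)) != len(self.snps):
            raise ValueError("SNP IDs are not unique")
        if (self.chrom is None) != (self.pos is None):
            raise ValueError("chrom and pos must be given together")
        for name in ("chrom", "pos", "ref", "alt"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val)
                if val.shape != (len(self.snps),):
                    raise ValueError(f"{name} must have one entry per SNP")
                setattr(self, name, val)

    # -- basic properties -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean samples × SNPs mask, True where the call is missing."""
        return self.dosage == MISSING

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            dosage=self.dosage.copy(),
            samples=list(self.samples),
            snps=list(self.snps),
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            dosage=self.dosage[idx],
            samples=[self.samples[i] for i in idx],
            snps=list(self.snps),
        )

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        sub = lambda a: None if a is None else a[idx]
        return replace(
            self,
            dosage=self.dosage[:, idx],
            samples=list(self.samples),
            snps=[self.snps[i] for i in idx],
            chrom=sub(self.chrom),
            pos=sub(self.pos),
            ref=sub(self.ref),
            alt=sub(self.alt),
        )


def allele_frequency(gm: GenotypeMatrix) -> np.ndarray:
    """Per-SNP frequency of the coded (dosage-counted) allele.

    f = (Σ dosage) / (2 · n_nonmissing), NaN for all-missing columns.
    """
    obs = gm.dosage != MISSING
    n = obs.sum(axis=0)
    total = np.where(obs, gm.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, total / (2.0 * n), np.nan)


def maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency, min(f, 1−f) over non-missing calls."""
    f = allele_frequency(gm)
    return np.minimum(f, 1.0 - f)


def recode_to_minor(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, np.ndarray]:
    """Flip SNPs whose coded allele is the major allele so dosage counts the minor allele.

    A SNP is flipped (d → 2−d on non-missing entries) when its coded-allele
    frequency is strictly greater than 0.5; a frequency of exactly 0.5 is
    left unchanged so the operation is deterministic and order-independent.

    Returns the recoded matrix and a boolean per-SNP flip record so callers
    can map results back to the original coding. Idempotent: applying it to
    its own output flips nothing.
    """
    f = allele_frequency(gm)
    flips = np.nan_to_num(f, nan=0.0) > 0.5
    out = gm.copy()
    if flips.any():
        cols = out.dosage[:, flips]
        obs = cols != MISSING
        cols[obs] = 2 - cols[obs]
        out.dosage[:, flips] = cols
        if out.ref is not None and out.alt is not None:
            r = out.ref.copy()
            out.ref = np.where(flips, out.alt, out.ref)
            out.alt = np.where(flips, r, out.alt)
    return out, flips


# ---------------------------------------------------------------------------
# VCF I/O (pysam)
# ---------------------------------------------------------------------------

def read_vcf(path: str, skip_nonbiallelic: bool = True) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a dosage matrix.

    ``0/0``→0, ``0/1``/``1/0``→1, ``1/1``→2, ``./.``→MISSING. Phased
    separators are accepted and treated as unphased. Dosage counts the ALT
    allele as coded in the file; use :func:`recode_to_minor` for
    minor-allele orientation.

    Sites that are not biallelic SNPs are skipped with a logged count when
    ``skip_nonbiallelic`` is True (the default), otherwise they raise.
    """
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise GenotypeFormatError(f"cannot parse VCF {path!r}: {exc}") from exc
    samples = list(vf.header.samples)
    rows: list[list[int]] = []
    snps: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    n_skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        biallelic_snp = (
            len(alts) == 1 and len(rec.ref) == 1 and len(alts[0]) == 1
            and rec.ref in "ACGT" and alts[0] in "ACGT"
        )
        if not biallelic_snp:
            if skip_nonbiallelic:
                n_skipped += 1
                continue
            raise GenotypeFormatError(
                f"non-biallelic or non-SNP record at {rec.chrom}:{rec.pos}"
            )
        col: list[int] = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or all(a is None for a in gt):
                col.append(MISSING)
                continue
            if len(gt) != 2 or any(a is None for a in gt):
                raise GenotypeFormatError(
                    f"sample {s!r} is not diploid at {rec.chrom}:{rec.pos} "
                    f"(GT has {len(gt)} allele(s))"
                )
            col.append(int(gt[0]) + int(gt[1]))
        rows.append(col)
        snps.append(rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}")
        chrom.append(str(rec.chrom))
        pos.append(int(rec.pos))
        ref.append(rec.ref)
        alt.append(alts[0])
    vf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    dosage = (
        np.array(rows, dtype=np.int8).T
        if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        dosage=dosage,
        samples=samples,
        snps=snps,
        chrom=np.array(chrom, dtype=object) if snps else None,
        pos=np.array(pos, dtype=np.int64) if snps else None,
        ref=np.array(ref, dtype=object) if snps else None,
        alt=np.array(alt, dtype=object) if snps else None,
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file (GT field only).

    When chromosome/position labels are absent, a placeholder contig "0"
    with positions 1..n_snps is written and flagged in the header; REF/ALT
    default to A/C when unknown. Output is byte-stable for a fixed input.
    """
    placeholder = gm.chrom is None
    chrom = np.full(gm.n_snps, "0", dtype=object) if placeholder else gm.chrom
    pos = np.arange(1, gm.n_snps + 1) if placeholder else gm.pos
    ref = gm.ref if gm.ref is not None else np.full(gm.n_snps, "A", dtype=object)
    alt = gm.alt if gm.alt is not None else np.full(gm.n_snps, "C", dtype=object)
    lines = ["##fileformat=VCFv4.2"]
    if placeholder:
        lines.append(
            "##ldknni_placeholder_coordinates=contig and positions are "
            "synthetic (input carried no coordinates)"
        )
    for c in dict.fromkeys(str(x) for x in chrom):
        lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.samples)
    )
    for j in range(gm.n_snps):
        gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.dosage[:, j])
        row = (
            f"{chrom[j]}\t{int(pos[j])}\t{gm.snps[j]}\t{ref[j]}\t{alt[j]}"
            f"\t.\t.\t.\tGT"
        )
        lines.append(row + ("\t" + gts if gm.n_samples else ""))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Plain numeric matrix I/O
# ---------------------------------------------------------------------------

def _is_int(tok: str) -> bool:
    try:
        int(tok)
    except ValueError:
        return False
    return True


def read_numeric(path: str) -> GenotypeMatrix:
    """Read a tab-delimited dosage matrix (one row per sample, −1 missing).

    A header row of SNP IDs and a leading column of sample IDs are
    auto-detected (any non-integer token marks them). Lines starting with
    ``#`` are treated as comments. Values outside {−1, 0, 1, 2} are
    rejected with their (row, column) coordinates.
    """
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    lines = [(i + 1, ln) for i, ln in enumerate(raw) if ln and not ln.startswith("#")]
    if not lines:
        raise GenotypeFormatError(f"{path!r}: no data lines")
    tokens = [(ln_no, ln.split("\t")) for ln_no, ln in lines]
    has_header = not all(_is_int(t) for t in tokens[0][1])
    body = tokens[1:] if has_header else tokens
    if not body:
        raise GenotypeFormatError(f"{path!r}: header but no data rows")
    has_ids = any(not _is_int(row[0]) for _, row in body)
    snp_ids = None
    if has_header:
        hdr = tokens[0][1]
        snp_ids = hdr[1:] if (has_ids and len(hdr) == len(body[0][1])) else hdr
    width = len(body[0][1])
    data = np.empty((len(body), width - (1 if has_ids else 0)), dtype=np.int8)
    sample_ids: list[str] = []
    for r, (ln_no, row) in enumerate(body):
        if len(row) != width:
            raise GenotypeFormatError(
                f"{path!r}: ragged row at line {ln_no} "
                f"({len(row)} fields, expected {width})"
            )
        vals = row[1:] if has_ids else row
        sample_ids.append(row[0] if has_ids else f"S{r + 1}")
        for c, tok in enumerate(vals):
            if not _is_int(tok):
                raise GenotypeFormatError(
                    f"{path!r}: non-integer value {tok!r} at line {ln_no}, "
                    f"column {c + 1}"
                )
            v = int(tok)
            if v not in _VALID_CODES:
                raise GenotypeFormatError(
                    f"{path!r}: invalid dosage {v} at row {r + 1}, column {c + 1} "
                    "(expected -1, 0, 1 or 2)"
                )
            data[r, c] = v
    if snp_ids is None:
        snp_ids = [f"M{j + 1}" for j in range(data.shape[1])]
    if len(snp_ids) != data.shape[1]:
        raise GenotypeFormatError(
            f"{path!r}: header has {len(snp_ids)} SNP IDs for {data.shape[1]} columns"
        )
    return GenotypeMatrix(dosage=data, samples=sample_ids, snps=snp_ids)


def write_numeric(gm: GenotypeMatrix, path: str, header: bool = True) -> None:
    """Write the tab-delimited dosage dialect (with SNP header + sample IDs)."""
    with open(path, "w") as fh:
        if header:
            fh.write("sample\t" + "\t".join(gm.snps) + "\n")
            for i, sid in enumerate(gm.samples):
                fh.write(sid + "\t" + "\t".join(map(str, gm.dosage[i])) + "\n")
        else:
            for i in range(gm.n_samples):
                fh.write("\t".join(map(str, gm.dosage[i])) + "\n")


def read_auto(path: str) -> GenotypeMatrix:
    """Dispatch on extension: .vcf/.vcf.gz → VCF, anything else → numeric."""
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return read_vcf(p)
    return read_numeric(p)


def write_auto(gm: GenotypeMatrix, path: str) -> None:
    p = str(path)
    if p.endswith(".vcf"):
        write_vcf(gm, p)
    else:
        write_numeric(gm, p)
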