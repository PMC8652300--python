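"""Genotype, voxel and table I/O.

Containers
----------
``GenotypeMatrix`` holds a samples x variants effect-allele dosage matrix
(int8; 0/1/2 with -1 as the missing sentinel) plus ordered variant metadata.
``VoxelMatrix`` holds a subjects x in-mask-voxels gray-matter matrix with the
shared 3-D mask and affine.

Formats
-------
VCF v4.2 is read through cyvcf2 (effect allele = ALT); PLINK bed/bim/fam is
read and written with a minimal built-in codec for the standard 2-bit bed
encoding (SNP-major, magic ``6c 1b 01``).  Coordinates are 1-based inclusive
throughout.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "SNPRecord",
    "GenotypeMatrix",
    "VoxelMatrix",
    "ParseError",
    "read_genotypes",
    "write_vcf",
    "write_plink",
    "read_gray_matter",
    "write_gray_matter",
]


class ParseError(ValueError):
    """Raised when an on-disk file does not conform to its declared format."""


@dataclasses.dataclass(frozen=True)
class SNPRecord:
    """A variant: id, chromosome, 1-based position and allele pair."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: pos must be >= 1")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.id}: effect and other allele identical")


@dataclasses.dataclass
class GenotypeMatrix:
    sample_ids: list[str]
    variants: list[SNPRecord]
    dosage: np.ndarray  # (n_samples, n_variants) int8, MISSING = -1

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage shape does not match sample/variant counts")
        ok = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def effect_allele_freq(self) -> np.ndarray:
        """Per-variant effect-allele frequency over non-missing calls."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        return np.asarray(d.mean(axis=0) / 2.0)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            variants=[self.variants[j] for j in vi],
            dosage=self.dosage[np.ix_(si, vi)],
        )

    def flip_variant(self, j: int) -> None:
        """Swap effect/other allele at column j; dosage d -> 2 - d."""
        v = self.variants[j]
        self.variants[j] = SNPRecord(v.id, v.chrom, v.pos, v.other_allele, v.effect_allele)
        col = self.dosage[:, j]
        obs = col != MISSING
        col[obs] = 2 - col[obs]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises opaque errors
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[SNPRecord] = []
    cols: list[np.ndarray] = []
    seen: set[str] = set()
    for line_no, rec in enumerate(vcf, start=1):
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if vid in seen:
            raise ParseError(f"duplicate variant id {vid!r} (record {line_no})")
        seen.add(vid)
        alt = rec.ALT[0] if rec.ALT else "."
        variants.append(SNPRecord(vid, str(rec.CHROM), int(rec.POS), alt, rec.REF))
        gt = np.asarray(rec.genotype.array())[:, :2]
        dose = np.where((gt < 0).any(axis=1), MISSING, (gt > 0).sum(axis=1))
        cols.append(dose.astype(np.int8))
    if not variants:
        raise ParseError(f"no variant records in {path}")
    return GenotypeMatrix(samples, variants, np.column_stack(cols))


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with the effect allele as ALT."""
    path = Path(path)
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = dict.fromkeys(v.chrom for v in G.variants)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        for j, v in enumerate(G.variants):
            calls = "\t".join(gt_code[int(d)] for d in G.dosage[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.other_allele}\t"
                     f"{v.effect_allele}\t.\t.\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------
# bed 2-bit codes (SNP-major): 00 hom a1, 01 missing, 10 het, 11 hom a2.
# bim a1 is taken as the effect allele, so dosage counts a1 copies.

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
_CODE_TO_DOSE = {0b00: 2, 0b01: MISSING, 0b10: 1, 0b11: 0}
_DOSE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _read_plink(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"iid": str})
    if bim["id"].duplicated().any():
        dups = bim.loc[bim["id"].duplicated(), "id"].tolist()
        raise ParseError(f"duplicate variant ids in bim: {dups}")
    variants = [SNPRecord(r.id, str(r.chrom), int(r.pos), r.a1, r.a2)
                for r in bim.itertuples()]
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ParseError(f"{prefix}.bed: bad magic, not a SNP-major bed file")
    stride = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != stride * m:
        raise ParseError(f"{prefix}.bed: size mismatch for {n} samples x {m} variants")
    blocks = body.reshape(m, stride)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, stride * 4)[:, :n]
    lut = np.full(4, MISSING, dtype=np.int8)
    for c, d in _CODE_TO_DOSE.items():
        lut[c] = d
    dosage = lut[codes].T.copy()
    return GenotypeMatrix(list(fam["iid"]), variants, dosage)


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in G.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.effect_allele}\t{v.other_allele}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in G.sample_ids:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")
    n = G.n_samples
    stride = (n + 3) // 4
    code = np.empty((G.n_variants, stride * 4), dtype=np.uint8)
    code[:] = _DOSE_TO_CODE[0]
    lut = np.zeros(256, dtype=np.uint8)
    for d, c in _DOSE_TO_CODE.items():
        lut[d & 0xFF] = c
    code[:, :n] = lut[G.dosage.T.view(np.uint8)]
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (code.reshape(G.n_variants, stride, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF or a PLINK bed/bim/fam fileset.

    ``path`` is the VCF file or the PLINK prefix; ``format`` in
    {"vcf", "plink"} is inferred from the name when omitted.  Dosage counts
    the effect allele (VCF: ALT; PLINK: bim a1); variant order is preserved.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz"} else "plink"
    if format == "vcf":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_vcf(path)
    if format == "plink":
        if not path.with_suffix(".bed").exists():
            raise FileNotFoundError(path.with_suffix(".bed"))
        return _read_plink(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Gray matter volumes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VoxelMatrix:
    subject_ids: list[str]
    mask: np.ndarray          # 3-D bool
    data: np.ndarray          # (n_subjects, n_mask_voxels)
    affine: np.ndarray        # 4x4

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.subject_ids), int(self.mask.sum())):
            raise ValueError("data columns must equal mask voxel count")


def read_gray_matter(
    paths: list[str | Path],
    mask_threshold: float = 0.0,
    subject_ids: list[str] | None = None,
) -> VoxelMatrix:
    """Stack gray-matter volumes into a subjects x voxels matrix.

    The mask keeps voxels whose across-subject mean exceeds
    ``mask_threshold``; all volumes must share shape and affine.
    """
    import nibabel as nib

    if not paths:
        raise ValueError("no volumes given")
    imgs = [nib.load(str(p)) for p in paths]
    shape, affine = imgs[0].shape, imgs[0].affine
    for p, img in zip(paths, imgs):
        if img.shape != shape or not np.allclose(img.affine, affine):
            raise ValueError(f"shape/affine mismatch: {p}")
    vols = np.stack([np.asarray(img.get_fdata(), dtype=np.float64) for img in imgs])
    mask = vols.mean(axis=0) > mask_threshold
    if not mask.any():
        raise ValueError("empty mask: threshold above all voxel means")
    if subject_ids is None:
        subject_ids = [Path(p).name.split(".")[0] for p in paths]
    return VoxelMatrix(subject_ids, mask, vols[:, mask], np.asarray(affine))


def write_gray_matter(V: VoxelMatrix, out_dir: str | Path, prefix: str = "gm") -> list[Path]:
    """Write one NIfTI volume per subject (zeros outside the mask)."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sid in enumerate(V.subject_ids):
        vol = np.zeros(V.mask.shape, dtype=np.float32)
        vol[V.mask] = V.data[i]
        p = out_dir / f"{prefix}_{sid}.nii"
        nib.save(nib.Nifti1Image(vol, V.affine), str(p))
        paths.append(p)
    return paths
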