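"""Readers and writers for the on-disk formats the pipeline touches.

Conventions
-----------
Peaks and all interval output use the BED convention (0-based, half-open).
Variants use the VCF convention (1-based positions).  The single bridge
between the two is :func:`variant_to_interval`.

The peak-by-cell matrix is stored as the usual single-cell triplet:
MatrixMarket counts (peaks as rows), a BED file of peaks, and a TSV of
barcodes with per-cell metadata.  Accessibility is unstranded, so peaks do
not carry strand; promoters (separate table) do.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: The fixed donor age groups of the cohort design.
AGE_GROUPS = ("30wkGA", "3yo", "30yo")

BARCODE_COLUMNS = [
    "barcode",
    "donor_id",
    "age_group",
    "sex",
    "cluster",
    "usable_reads",
    "library_complexity",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class Peak:
    """An accessible-chromatin peak (pseudo-locus).

    A peak stands for the set of minimal accessible loci it spans; counts
    are aggregated at this level.  Coordinates are 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"peak {self.id}: start {self.start} >= end {self.end}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class PeakSet:
    """An ordered collection of peaks with unique ids."""

    def __init__(self, peaks: list[Peak]):
        self.peaks = list(peaks)
        self._index = {p.id: i for i, p in enumerate(self.peaks)}
        if len(self._index) != len(self.peaks):
            raise ValueError("duplicate peak ids in PeakSet")

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def index_of(self, peak_id: str) -> int:
        return self._index[peak_id]

    def subset(self, indices) -> "PeakSet":
        return PeakSet([self.peaks[i] for i in indices])


@dataclass
class CellRecord:
    """Per-cell metadata.

    ``library_complexity`` (C_j) is the estimated number of distinct
    molecules in the cell's library; ``usable_reads`` (k_j) the number of
    unique non-mitochondrial reads.  Together they determine the sequencing
    probability of any one fragment.
    """

    barcode: str
    donor_id: str
    age_group: str
    sex: str
    cluster: str
    usable_reads: int
    library_complexity: float

    def __post_init__(self):
        if self.age_group not in AGE_GROUPS:
            raise ValueError(
                f"age_group {self.age_group!r} not one of {AGE_GROUPS}"
            )
        if self.library_complexity < 1:
            raise ValueError("library_complexity must be >= 1")
        if self.usable_reads < 0:
            raise ValueError("usable_reads must be >= 0")


class PeakMatrix:
    """Sparse non-negative peak-by-cell fragment counts plus metadata."""

    def __init__(self, counts: sp.spmatrix, peaks: PeakSet, cells: list[CellRecord]):
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(peaks), len(cells)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(peaks)} peaks x {len(cells)} cells"
            )
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("negative count entry")
        if counts.nnz and np.any(counts.data != np.round(counts.data)):
            raise ValueError("non-integer count entry")
        counts = counts.astype(np.int64)
        barcodes = [c.barcode for c in cells]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate cell barcodes")
        self.counts = counts
        self.peaks = peaks
        self.cells = list(cells)

    @property
    def shape(self):
        return self.counts.shape

    def cell_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "barcode": c.barcode,
                    "donor_id": c.donor_id,
                    "age_group": c.age_group,
                    "sex": c.sex,
                    "cluster": c.cluster,
                    "usable_reads": c.usable_reads,
                    "library_complexity": c.library_complexity,
                }
                for c in self.cells
            ]
        )

    def subset_cells(self, indices) -> "PeakMatrix":
        indices = np.asarray(indices)
        return PeakMatrix(
            self.counts[:, indices], self.peaks, [self.cells[i] for i in indices]
        )

    def subset_peaks(self, indices) -> "PeakMatrix":
        indices = np.asarray(indices)
        return PeakMatrix(self.counts[indices, :], self.peaks.subset(indices), self.cells)


@dataclass
class PWM:
    """A position weight matrix: per-position base probabilities over ACGT."""

    name: str
    matrix: np.ndarray  # width x 4
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


@dataclass
class VariantRecord:
    """A sequence variant with cohort count and per-population frequencies."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    allele_count: int
    pop_freqs: dict[str, float] = field(default_factory=dict)
    ppa: float | None = None

    def __post_init__(self):
        if self.pos <= 0:
            raise ValueError(f"variant position must be positive, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for pop, f in self.pop_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} for {pop} outside [0,1]")
        if self.ppa is not None and not 0.0 <= self.ppa <= 1.0:
            raise ValueError(f"ppa {self.ppa} outside [0,1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def variant_to_interval(variant: VariantRecord) -> tuple[str, int, int]:
    """Convert a 1-based variant position to a 0-based half-open interval
    spanning the reference allele."""
    start = variant.pos - 1
    return variant.chrom, start, start + len(variant.ref)


# ---------------------------------------------------------------------------
# Peak matrix triplet


def write_peak_matrix(matrix: PeakMatrix, matrix_path, peaks_path, barcodes_path):
    scipy.io.mmwrite(str(matrix_path), matrix.counts.tocoo(), field="integer")
    with open(peaks_path, "w") as fh:
        for p in matrix.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\n")
    matrix.cell_table().to_csv(barcodes_path, sep="\t", index=False)


def read_peak_matrix(matrix_path, peaks_path, barcodes_path) -> PeakMatrix:
    """Read the (MatrixMarket, peaks BED, barcodes TSV) triplet.

    Peaks are rows.  A transposed matrix is rejected on the dimension
    check, never silently flipped.
    """
    counts = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    peaks = read_peaks_bed(peaks_path)
    bc = pd.read_csv(barcodes_path, sep="\t")
    missing = set(BARCODE_COLUMNS) - set(bc.columns)
    if missing:
        raise FormatError(f"barcodes file missing columns: {sorted(missing)}")
    if counts.shape[0] != len(peaks) or counts.shape[1] != len(bc):
        raise FormatError(
            f"matrix is {counts.shape} but peaks file has {len(peaks)} rows "
            f"and barcodes file has {len(bc)} rows"
        )
    cells = [
        CellRecord(
            barcode=str(r.barcode),
            donor_id=str(r.donor_id),
            age_group=str(r.age_group),
            sex=str(r.sex),
            cluster=str(r.cluster),
            usable_reads=int(r.usable_reads),
            library_complexity=float(r.library_complexity),
        )
        for r in bc.itertuples(index=False)
    ]
    return PeakMatrix(counts, peaks, cells)


def read_peaks_bed(path) -> PeakSet:
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line {i + 1}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            pid = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            peaks.append(Peak(chrom, start, end, pid))
    return PeakSet(peaks)


def write_peaks_bed(peaks: PeakSet, path):
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_pwms(meme_path) -> list[PWM]:
    """Parse a MEME minimal-format motif file into PWMs.

    Rows not summing to 1 within 1e-3 raise :class:`FormatError`; smaller
    drift is renormalized.
    """
    with open(meme_path) as fh:
        lines = fh.readlines()
    background = np.full(4, 0.25)
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            tokens = lines[i].split()
            freq = {tokens[k]: float(tokens[k + 1]) for k in range(0, len(tokens), 2)}
            background = np.array([freq[b] for b in "ACGT"])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i >= len(lines):
                raise FormatError(f"motif {name}: missing letter-probability matrix")
            header = lines[i].strip()
            m = re.search(r"w=\s*(\d+)", header)
            if not m:
                raise FormatError(f"motif {name}: cannot parse matrix width")
            width = int(m.group(1))
            rows = []
            for _ in range(width):
                i += 1
                vals = [float(x) for x in lines[i].split()]
                if len(vals) != 4:
                    raise FormatError(f"motif {name}: matrix row has {len(vals)} columns")
                s = sum(vals)
                if abs(s - 1.0) > 1e-3:
                    raise FormatError(f"motif {name}: matrix row sums to {s:.4f}, not 1")
                rows.append([v / s for v in vals])
            mat = np.array(rows)
            pwms.append(PWM(name=name, matrix=mat, background=background.copy()))
        i += 1
    if not pwms:
        raise FormatError("no motifs found in MEME file")
    return pwms


def write_pwms(pwms: list[PWM], path):
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = pwms[0].background
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(*bg)
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Variant tables (VCF-like TSV, 1-based positions)

_VARIANT_FIXED = ["chrom", "pos", "ref", "alt", "allele_count"]


def read_variants(table_path) -> list[VariantRecord]:
    """Read a variant TSV; every non-fixed, non-ppa column is a population
    allele frequency."""
    df = pd.read_csv(table_path, sep="\t", dtype={"chrom": str})
    missing = set(_VARIANT_FIXED) - set(df.columns)
    if missing:
        raise FormatError(f"variant table missing columns: {sorted(missing)}")
    pop_cols = [c for c in df.columns if c not in _VARIANT_FIXED + ["ppa"]]
    out = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        ppa = d.get("ppa")
        if ppa is not None and pd.isna(ppa):
            ppa = None
        freqs = {c: float(d[c]) for c in pop_cols if not pd.isna(d[c])}
        out.append(
            VariantRecord(
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=str(d["ref"]).upper(),
                alt=str(d["alt"]).upper(),
                allele_count=int(d["allele_count"]),
                pop_freqs=freqs,
                ppa=None if ppa is None else float(ppa),
            )
        )
    return out


def write_variants(variants: list[VariantRecord], path):
    pops = sorted({p for v in variants for p in v.pop_freqs})
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "allele_count": v.allele_count,
        }
        for p in pops:
            row[p] = v.pop_freqs.get(p, np.nan)
        row["ppa"] = np.nan if v.ppa is None else v.ppa
        rows.append(row)
    cols = _VARIANT_FIXED + pops + ["ppa"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Link BEDPE

_LINK_HEADER = [
    "#chromA",
    "startA",
    "endA",
    "chromB",
    "startB",
    "endB",
    "name",
    "score",
    "strandA",
    "strandB",
    "mean_score",
    "n_runs",
    "t_p",
    "retained",
]


def write_links(links, path):
    """Write co-accessibility links as BEDPE plus merge-statistic columns.

    Anchors are ordered so (chromA, startA) <= (chromB, startB); unordered
    input is corrected and logged.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_LINK_HEADER) + "\n")
        for ln in links:
            a, b = ln.peak_a, ln.peak_b
            if (a.chrom, a.start) > (b.chrom, b.start):
                logger.warning("link %s-%s had unordered anchors; swapped", a.id, b.id)
                a, b = b, a
            fh.write(
                "\t".join(
                    [
                        a.chrom,
                        str(a.start),
                        str(a.end),
                        b.chrom,
                        str(b.start),
                        str(b.end),
                        f"{a.id}|{b.id}",
                        f"{ln.mean_score:.6g}",
                        ".",
                        ".",
                        repr(float(ln.mean_score)),
                        str(ln.n_runs),
                        repr(float(ln.t_p)) if ln.t_p is not None else "NA",
                        "1" if ln.retained else "0",
                    ]
                )
                + "\n"
            )


def read_links(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df.columns = [c.lstrip("#") for c in df.columns]
    return df


# ---------------------------------------------------------------------------
# FASTA (simple uncompressed genome), promoter tables, k-mer weights


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_promoters(path) -> pd.DataFrame:
    """Promoter table: gene, chrom, tss (0-based position), strand, biotype."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene", "chrom", "tss", "strand", "biotype"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"promoter table missing columns: {sorted(missing)}")
    return df


def write_promoters(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def read_kmer_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"kmer", "weight"} <= set(df.columns):
        raise FormatError("k-mer weight table needs columns kmer, weight")
    return df


def write_kmer_weights(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)
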