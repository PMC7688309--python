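"""Regulatory-variant scoring.

Three layers:

* cohort filters — drop singletons (allele count 1) and indels longer than
  3 bp; flag common variants (folded minor-allele frequency > 0.01 in at
  least one population);
* allele-aware motif scanning — log-odds PWM scores in bits against a
  0-order background, with exact match p-values computed by dynamic
  programming over the integer-rounded score distribution (scale x1000);
  a variant has allelic TF binding if at least one allele carries at least
  one significant motif placement overlapping the variant;
* sequence-model delta scores — the difference between the summed 11-mer
  weights of the alternate and reference 19-bp windows (+/- 9 bp) around a
  SNV, standardized against a null obtained by permuting the weight values
  across k-mers and re-scoring every variant, with BH correction across
  variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PWM, PeakSet, VariantRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGT", "TGCA")
_SCALE = 1000  # integer rounding scale for exact score distributions
_NEG = np.iinfo(np.int64).min // 4  # sentinel for log2(0)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Cohort filters


def filter_variants(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Drop singletons and indels longer than 3 bp; SNVs always pass the
    length rule."""
    out = []
    for v in variants:
        if v.allele_count == 1:
            continue
        if abs(len(v.ref) - len(v.alt)) > 3:
            continue
        out.append(v)
    return out


def is_common(variant: VariantRecord, maf_threshold: float = 0.01) -> bool | None:
    """Common iff the folded MAF min(f, 1-f) exceeds *maf_threshold*
    (strict) in any population; None if no frequency data."""
    if not variant.pop_freqs:
        return None
    return any(min(f, 1.0 - f) > maf_threshold for f in variant.pop_freqs.values())


# ---------------------------------------------------------------------------
# PWM scanning with exact p-values


def _int_score_matrix(pwm: PWM) -> np.ndarray:
    """Integer-rounded log-odds scores (bits x SCALE); log2(0) -> sentinel."""
    with np.errstate(divide="ignore"):
        bits = np.log2(pwm.matrix) - np.log2(pwm.background[None, :])
    ints = np.full(bits.shape, _NEG, dtype=np.int64)
    finite = np.isfinite(bits)
    ints[finite] = np.round(bits[finite] * _SCALE).astype(np.int64)
    return ints


def _score_distribution(ints: np.ndarray, background: np.ndarray):
    """Exact distribution of the integer motif score under the background.

    Returns (sorted scores, tail probabilities P(X >= score)).  Paths through
    a zero-probability base have score -inf and drop out of the finite
    mass, so tail sums stay correct.
    """
    dist = {0: 1.0}
    for row in ints:
        nxt: dict[int, float] = {}
        for s, pr in dist.items():
            for b in range(4):
                if row[b] == _NEG:
                    continue  # -inf path: never reaches any finite threshold
                key = s + int(row[b])
                nxt[key] = nxt.get(key, 0.0) + pr * background[b]
        dist = nxt
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    tails = np.cumsum(probs[::-1])[::-1]
    return scores, tails


def _tail_p(scores: np.ndarray, tails: np.ndarray, s: int) -> float:
    i = np.searchsorted(scores, s, side="left")
    if i >= len(scores):
        return 0.0
    return float(tails[i])


@dataclass
class MotifHit:
    pwm: str
    strand: str
    offset: int
    score_bits: float
    p: float


def _pwm_variants_of(pwm: PWM) -> list[tuple[str, PWM]]:
    """(strand, oriented PWM) for forward and reverse-complement scanning."""
    rc = PWM(
        name=pwm.name,
        matrix=pwm.matrix[::-1, ::-1].copy(),
        background=pwm.background[::-1].copy(),
    )
    return [("+", pwm), ("-", rc)]


def pwm_best_hits(sequence: str, pwm: PWM, p_threshold: float = 1e-4) -> list[MotifHit]:
    """All motif placements on either strand with exact match p < threshold.

    Offsets are 0-based positions of the placement's left edge on the given
    sequence; offsets covering an N are skipped.
    """
    sequence = sequence.upper()
    w = pwm.width
    hits: list[MotifHit] = []
    for strand, oriented in _pwm_variants_of(pwm):
        ints = _int_score_matrix(oriented)
        scores, tails = _score_distribution(ints, oriented.background)
        for off in range(0, len(sequence) - w + 1):
            sub = sequence[off : off + w]
            if any(b not in _BASE_INDEX for b in sub):
                continue
            total = 0
            dead = False
            for i, b in enumerate(sub):
                s = ints[i, _BASE_INDEX[b]]
                if s == _NEG:
                    dead = True
                    break
                total += int(s)
            if dead:
                continue
            p = _tail_p(scores, tails, total)
            if p < p_threshold:
                hits.append(
                    MotifHit(pwm.name, strand, off, total / _SCALE, p)
                )
    return hits


def _allele_window(genome: dict[str, str], variant: VariantRecord, allele: str, flank: int) -> tuple[str, int]:
    """Sequence with *allele* substituted, plus *flank* bases each side.

    Returns (sequence, genome start of the window, 0-based).
    """
    chrom = genome[variant.chrom]
    pos0 = variant.pos - 1
    if pos0 < 0 or pos0 + len(variant.ref) > len(chrom):
        raise ValueError(f"variant {variant.key} outside genome bounds")
    left = chrom[max(0, pos0 - flank) : pos0]
    right = chrom[pos0 + len(variant.ref) : pos0 + len(variant.ref) + flank]
    if len(left) < flank or len(right) < flank:
        raise ValueError(f"variant {variant.key} too close to a contig edge")
    return left + allele + right, pos0 - flank


def scan_variant_motifs(
    variant: VariantRecord,
    genome: dict[str, str],
    pwms: list[PWM],
    p_threshold: float = 1e-4,
) -> dict:
    """Per-allele motif hits in a window covering every placement that
    overlaps the variant; allelic_binding is the either-allele rule."""
    hits = {"ref": [], "alt": []}
    for pwm in pwms:
        flank = pwm.width - 1
        for name, allele in (("ref", variant.ref), ("alt", variant.alt)):
            seq, _ = _allele_window(genome, variant, allele, flank)
            hits[name].extend(pwm_best_hits(seq, pwm, p_threshold))
    return {
        "ref_hits": hits["ref"],
        "alt_hits": hits["alt"],
        "allelic_binding": bool(hits["ref"] or hits["alt"]),
    }


# ---------------------------------------------------------------------------
# k-mer delta scores


@dataclass
class KmerWeightTable:
    """Weights for k-mers (uppercase ACGT); optional reverse-complement
    fallback for absent keys."""

    weights: dict[str, float]
    k: int = 11
    use_revcomp: bool = True

    def __post_init__(self):
        for km in self.weights:
            if len(km) != self.k or any(b not in _BASE_INDEX for b in km):
                raise ValueError(f"bad k-mer key {km!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, k: int = 11, use_revcomp: bool = True):
        return cls(dict(zip(df["kmer"].str.upper(), df["weight"].astype(float))), k, use_revcomp)

    def lookup(self, kmer: str) -> float:
        if kmer in self.weights:
            return self.weights[kmer]
        if self.use_revcomp:
            rc = revcomp(kmer)
            if rc in self.weights:
                return self.weights[rc]
        raise KeyError(f"k-mer {kmer!r} absent from weight table")


def _window_kmers(genome: dict[str, str], variant: VariantRecord, allele: str, k: int) -> list[str]:
    # +/- (k - 2) flanking gives a (2k - 3)-bp window: 19 bp for k = 11
    seq, _ = _allele_window(genome, variant, allele, k - 2)
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def delta_score(
    variant: VariantRecord, genome: dict[str, str], table: KmerWeightTable
) -> float:
    """Summed-weight difference alt - ref over the 19-bp (+/- 9) windows.

    Only defined for SNVs; each allele window of length 2k - 3 contributes
    its k - 1 constituent k-mers (9 for k = 11).
    """
    if not variant.is_snv:
        raise ValueError("delta scores are defined for SNVs only")
    ref_k = _window_kmers(genome, variant, variant.ref, table.k)
    alt_k = _window_kmers(genome, variant, variant.alt, table.k)
    try:
        ref_sum = sum(table.lookup(km) for km in ref_k)
        alt_sum = sum(table.lookup(km) for km in alt_k)
    except KeyError as e:
        raise ValueError(str(e)) from e
    return float(alt_sum - ref_sum)


def delta_null_test(
    variants: list[VariantRecord],
    genome: dict[str, str],
    table: KmerWeightTable,
    n_perm: int = 100,
    seed: int = 0,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Permutation z-scores for delta effects.

    Each permutation reassigns the weight-value multiset across all k-mers
    jointly and re-scores every SNV; z standardizes the observed delta by
    the per-variant null mean/sd, p is two-sided normal, q BH across
    variants.  Variants with sd_null = 0 report missing z/p/q.
    """
    keys = sorted(table.weights)
    key_index = {km: i for i, km in enumerate(keys)}
    values = np.array([table.weights[km] for km in keys])

    def indices(kmers):
        out = []
        for km in kmers:
            if km in key_index:
                out.append(key_index[km])
            elif table.use_revcomp and revcomp(km) in key_index:
                out.append(key_index[revcomp(km)])
            else:
                raise ValueError(f"k-mer {km!r} absent from weight table")
        return out

    snvs = [v for v in variants if v.is_snv]
    ref_idx = np.array([indices(_window_kmers(genome, v, v.ref, table.k)) for v in snvs])
    alt_idx = np.array([indices(_window_kmers(genome, v, v.alt, table.k)) for v in snvs])
    observed = values[alt_idx].sum(axis=1) - values[ref_idx].sum(axis=1)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(snvs)))
    for b in range(n_perm):
        perm = rng.permutation(values)
        null[b] = perm[alt_idx].sum(axis=1) - perm[ref_idx].sum(axis=1)
    mean_null = null.mean(axis=0)
    sd_null = null.std(axis=0, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_null > 0, (observed - mean_null) / sd_null, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "variant": [v.key for v in snvs],
            "delta": observed,
            "z": z,
            "p": p,
        }
    )
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["q"] = q
    out["significant"] = out["q"] < fdr
    return out


# ---------------------------------------------------------------------------
# Peak / credible-set overlap


def overlap_annotate(
    variants: list[VariantRecord],
    peaks: PeakSet,
    cell_type_access: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Annotate variants with the peaks they fall in.

    A 1-based position p overlaps a 0-based half-open peak [start, end)
    iff start <= p - 1 < end.  Annotations carry the accessible cell types
    of the peak (if provided) and the variant's PPA when present.
    """
    rows = []
    for v in variants:
        pos0 = v.pos - 1
        for pk in peaks:
            if pk.chrom == v.chrom and pk.start <= pos0 < pk.end:
                rows.append(
                    {
                        "variant": v.key,
                        "peak_id": pk.id,
                        "cell_types": ",".join(
                            (cell_type_access or {}).get(pk.id, [])
                        ),
                        "ppa": v.ppa,
                    }
                )
    return pd.DataFrame(rows, columns=["variant", "peak_id", "cell_types", "ppa"])
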