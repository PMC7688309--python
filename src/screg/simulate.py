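"""Synthetic cohorts, genomes, and variants with planted ground truth.

The generator emulates the structure of a three-age-group donor cohort
(premature ~30-week gestational age, ~3-year-old, ~30-year-old; three
donors per group) profiled by single-nucleus ATAC and RNA:

* per-cell chromatin counts are 0/1/2 per peak (two alleles), produced by a
  Bernoulli open-state draw at logistic(baseline + age shift + latent
  co-accessibility factor), thinned by the cell's sequencing probability
  s_j = 1 - (1 - 1/C_j)^{k_j} — the exact sampling model the accessibility
  estimator inverts, so the estimator is unbiased by construction;
* library complexity C_j is log-normal with a per-donor multiplicative
  shift (donors differ systematically in depth, which the corrected scores
  must not be confounded by), and reads k_j ~ Poisson(r * C_j);
* co-accessible peak modules share a per-cell latent factor of strength
  rho; age-dynamic peaks carry monotone per-age-group logit shifts;
* a small genome carries the peaks, protein-coding gene promoters, planted
  motif consensus occurrences, motif-disrupting and neutral variants, and
  an 11-mer weight table covering every variant window.

All randomness flows from one seed through named substreams, so any single
generator can be re-run reproducibly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .access import sequencing_probability
from .expression import ExpressionMatrix
from .io import AGE_GROUPS, PWM, CellRecord, Peak, PeakMatrix, PeakSet, VariantRecord

BASES = "ACGT"


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent generator derived from (seed, name)."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort; defaults are the study design."""

    # cohort
    n_donors_per_age: int = 3
    cells_per_donor: int = 250
    cell_types: dict[str, float] = field(
        default_factory=lambda: {"AT2": 0.5, "AT1": 0.3, "macrophage": 0.2}
    )
    # peak layout / genome
    n_peaks: int = 300
    peak_width: int = 400
    peak_gap: tuple[int, int] = (2000, 8000)
    chrom: str = "chr1"
    genome_length: int = 2_000_000
    # accessibility baselines
    base_logit_mean: float = -2.0
    base_logit_sd: float = 0.5
    marker_fraction: float = 0.10
    marker_logit_boost: float = 2.0
    # depth model
    complexity_lognormal: tuple[float, float] = (9.2, 0.5)
    donor_complexity_sd: float = 0.4
    reads_per_molecule: float = 1.0
    depth_sigma: float = 0.6  # per-cell lognormal spread of reads/molecule
    # planted co-accessibility modules
    n_coaccess_modules: int = 5
    module_size: int = 4
    module_rho: float = 0.6
    module_latent_sd: float = 2.0
    # planted age-dynamic peaks
    n_dynamic_peaks: int = 60
    dynamic_logit_shift: float = 0.9
    # genes / expression
    n_genes: int = 30
    n_nuclei_per_donor: int = 250
    expr_extra_umis: float = 0.6
    n_age_expr_genes: int = 5
    age_expr_shift: float = 0.15
    # variants
    n_disrupting_variants: int = 15
    n_neutral_variants: int = 30
    n_singleton_variants: int = 5
    n_long_indel_variants: int = 3
    n_credible_variants: int = 5
    motif_consensus: tuple[str, ...] = ("TGACTCAT", "GGGACTTTCC")
    motif_bonus: float = 4.0
    kmer_k: int = 11

    def validate(self):
        props = np.array(list(self.cell_types.values()))
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("cell-type proportions must sum to 1")
        if np.any(props < 0):
            raise ValueError("cell-type proportions must be >= 0")
        for name in (
            "n_donors_per_age",
            "cells_per_donor",
            "n_peaks",
            "n_genes",
            "n_dynamic_peaks",
            "n_coaccess_modules",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.module_rho < 1.0:
            raise ValueError("module_rho must be in [0, 1)")
        if not 0.0 <= self.marker_fraction <= 1.0:
            raise ValueError("marker_fraction must be a probability")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated cohort."""

    planted_link_pairs: set[tuple[str, str]]
    planted_dynamic_peaks: dict[str, str]  # peak id -> "up" | "down"
    planted_k: int
    motif_disrupting_variants: set[str]
    expressing_fraction_truth: dict[tuple[str, str, str], float]


@dataclass
class _Layout:
    peaks: PeakSet
    marker_type: dict[int, str]  # peak index -> cell type
    modules: list[list[int]]  # peak indices, first member = promoter peak
    dynamic: dict[int, str]  # peak index -> direction
    genes: pd.DataFrame  # gene, chrom, tss, strand, biotype, peak_index
    motif_sites: list[tuple[int, int, str]]  # (peak index, genome start, consensus)


def _layout(config: SimConfig, seed: int) -> _Layout:
    """Deterministic genome/peak layout shared by cohort and genome sims."""
    config.validate()
    rng = _rng(seed, "layout")
    lo, hi = config.peak_gap
    gaps = rng.integers(lo, hi, size=config.n_peaks)
    starts = 1000 + np.cumsum(gaps) + np.arange(config.n_peaks) * config.peak_width
    ends = starts + config.peak_width
    if config.n_peaks and ends[-1] + 1000 > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too short for "
            f"{config.n_peaks} peaks (need ~{ends[-1] + 1000})"
        )
    width = len(str(max(config.n_peaks, 1)))
    peaks = PeakSet(
        [
            Peak(config.chrom, int(s), int(e), f"peak{i:0{width}d}")
            for i, (s, e) in enumerate(zip(starts, ends))
        ]
    )

    order = rng.permutation(config.n_peaks)
    n_marker = int(round(config.marker_fraction * config.n_peaks))
    type_names = list(config.cell_types)
    marker_type = {int(i): type_names[k % len(type_names)] for k, i in enumerate(order[:n_marker])}

    # modules: blocks of consecutive non-marker peaks, spaced apart
    modules: list[list[int]] = []
    used = set(marker_type)
    cursor = 2
    span = max(config.module_size * 3, 10)
    for _ in range(config.n_coaccess_modules):
        while cursor + config.module_size < config.n_peaks and any(
            (cursor + t) in used for t in range(config.module_size)
        ):
            cursor += 1
        if cursor + config.module_size >= config.n_peaks:
            break
        members = list(range(cursor, cursor + config.module_size))
        modules.append(members)
        used.update(members)
        cursor += span

    # dynamic peaks among the remainder
    free = [i for i in range(config.n_peaks) if i not in used]
    rng.shuffle(free)
    dyn_idx = free[: config.n_dynamic_peaks]
    dynamic = {int(i): ("up" if k % 2 == 0 else "down") for k, i in enumerate(dyn_idx)}
    used.update(dyn_idx)

    # genes: module anchors first (planted links become promoter links)
    anchors = [m[0] for m in modules]
    other = [i for i in range(config.n_peaks) if i not in used][: config.n_genes - len(anchors)]
    gene_peaks = (anchors + other)[: config.n_genes]
    rows = []
    for g, pi in enumerate(gene_peaks):
        pk = peaks[pi]
        rows.append(
            {
                "gene": f"gene{g:03d}",
                "chrom": pk.chrom,
                "tss": int(pk.midpoint),
                "strand": "+" if rng.random() < 0.5 else "-",
                "biotype": "protein_coding",
                "peak_index": pi,
            }
        )
    genes = pd.DataFrame(rows)
    if len(genes) > 4:
        genes.loc[len(genes) - 1, "biotype"] = "lincRNA"  # exercised by promoter linking

    # motif occurrences inside peaks not used by modules (one per disrupting variant)
    motif_sites = []
    host = [i for i in range(config.n_peaks) if i not in {m for mod in modules for m in mod}]
    rng.shuffle(host)
    for k in range(config.n_disrupting_variants):
        cons = config.motif_consensus[k % len(config.motif_consensus)]
        pi = host[k % len(host)]
        pk = peaks[pi]
        off = int(rng.integers(50, config.peak_width - 50 - len(cons)))
        motif_sites.append((pi, pk.start + off, cons))

    return _Layout(peaks, marker_type, modules, dynamic, genes, motif_sites)


_DIR_PROFILE = {"up": (-1.0, 0.0, 1.0), "down": (1.0, 0.0, -1.0)}


def simulate_cohort(config: SimConfig, seed: int) -> tuple[PeakMatrix, ExpressionMatrix, SyntheticTruth]:
    """Generate (PeakMatrix, ExpressionMatrix, SyntheticTruth) for one cohort."""
    config.validate()
    lay = _layout(config, seed)
    rng = _rng(seed, "cohort")

    type_names = list(config.cell_types)
    props = np.array([config.cell_types[t] for t in type_names])
    mu, sigma = config.complexity_lognormal

    cells: list[CellRecord] = []
    type_idx = []
    age_idx = []
    donor_sex = {}
    donor_shift = {}
    d = 0
    for a, age in enumerate(AGE_GROUPS):
        for _ in range(config.n_donors_per_age):
            donor = f"D{age}_{d}"
            donor_sex[donor] = "M" if d % 2 == 0 else "F"
            donor_shift[donor] = rng.normal(0.0, config.donor_complexity_sd)
            for _ in range(config.cells_per_donor):
                t = int(rng.choice(len(type_names), p=props))
                C = max(1.0, float(rng.lognormal(mu + donor_shift[donor], sigma)))
                depth = float(rng.lognormal(np.log(config.reads_per_molecule), config.depth_sigma))
                k = int(rng.poisson(depth * C))
                cells.append(
                    CellRecord(
                        barcode=f"BC{len(cells):06d}",
                        donor_id=donor,
                        age_group=age,
                        sex=donor_sex[donor],
                        cluster=type_names[t],
                        usable_reads=k,
                        library_complexity=C,
                    )
                )
                type_idx.append(t)
                age_idx.append(a)
            d += 1
    n_cells = len(cells)
    type_idx = np.array(type_idx)
    age_idx = np.array(age_idx)

    # per-peak baselines and planted effects
    base = rng.normal(config.base_logit_mean, config.base_logit_sd, config.n_peaks)
    base_by_type = np.tile(base[:, None], (1, len(type_names)))
    for pi, t in lay.marker_type.items():
        base_by_type[pi, type_names.index(t)] += config.marker_logit_boost
    ageshift = np.zeros((config.n_peaks, len(AGE_GROUPS)))
    for pi, direction in lay.dynamic.items():
        ageshift[pi] = np.array(_DIR_PROFILE[direction]) * config.dynamic_logit_shift

    logit = base_by_type[:, type_idx] + ageshift[:, age_idx]
    if lay.modules:
        # standard factor parametrization: member peaks share loading
        # sqrt(rho) on a per-cell module factor plus idiosyncratic
        # sqrt(1 - rho) noise, so the pairwise latent correlation is rho;
        # module_latent_sd scales the whole latent term
        sd = config.module_latent_sd
        loading = np.zeros((config.n_peaks, len(lay.modules)))
        member_mask = np.zeros(config.n_peaks, dtype=bool)
        for m, members in enumerate(lay.modules):
            loading[members, m] = sd * np.sqrt(config.module_rho)
            member_mask[members] = True
        z = rng.standard_normal((len(lay.modules), n_cells))
        idio = rng.standard_normal((config.n_peaks, n_cells))
        logit = logit + loading @ z
        logit[member_mask] += sd * np.sqrt(1.0 - config.module_rho) * idio[member_mask]

    p_open = _sigmoid(logit)
    open_alleles = rng.binomial(2, p_open)
    s = sequencing_probability(
        np.array([c.library_complexity for c in cells]),
        np.array([c.usable_reads for c in cells]),
    )
    counts = rng.binomial(open_alleles, s[None, :])
    matrix = PeakMatrix(sp.csr_matrix(counts), lay.peaks, cells)

    # expression
    erng = _rng(seed, "expression")
    genes = list(lay.genes["gene"])
    truth_frac: dict[tuple[str, str, str], float] = {}
    base_frac = erng.uniform(0.05, 0.6, size=(len(genes), len(type_names)))
    age_genes = set(range(min(config.n_age_expr_genes, len(genes))))
    for gi, g in enumerate(genes):
        for ti, t in enumerate(type_names):
            for a, age in enumerate(AGE_GROUPS):
                f = base_frac[gi, ti]
                if gi in age_genes:
                    f = min(0.95, f + a * config.age_expr_shift)
                truth_frac[(g, t, age)] = float(f)

    meta_rows = []
    d = 0
    for a, age in enumerate(AGE_GROUPS):
        for _ in range(config.n_donors_per_age):
            donor = f"D{age}_{d}"
            for _ in range(config.n_nuclei_per_donor):
                t = int(erng.choice(len(type_names), p=props))
                meta_rows.append(
                    {
                        "barcode": f"RN{len(meta_rows):06d}",
                        "donor_id": donor,
                        "age_group": age,
                        "cluster": type_names[t],
                    }
                )
            d += 1
    meta = pd.DataFrame(meta_rows)
    n_nuclei = len(meta)
    t_of_nuc = np.array([type_names.index(c) for c in meta["cluster"]])
    a_of_nuc = np.array([AGE_GROUPS.index(c) for c in meta["age_group"]])
    expr = np.zeros((len(genes), n_nuclei), dtype=np.int64)
    for gi, g in enumerate(genes):
        f = np.array([truth_frac[(g, type_names[t], AGE_GROUPS[a])] for t, a in zip(t_of_nuc, a_of_nuc)])
        expressing = erng.random(n_nuclei) < f
        expr[gi, expressing] = 1 + erng.poisson(config.expr_extra_umis, expressing.sum())
    expression = ExpressionMatrix(sp.csr_matrix(expr), genes, meta)

    # truth
    pairs = set()
    for members in lay.modules:
        ids = [lay.peaks[i].id for i in members]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.add(tuple(sorted((ids[i], ids[j]))))
    dynamic = {lay.peaks[i].id: direction for i, direction in lay.dynamic.items()}
    variants = _make_variants(config, seed, lay)
    disrupting = {v.key for v, kind in variants if kind == "disrupting"}
    truth = SyntheticTruth(
        planted_link_pairs=pairs,
        planted_dynamic_peaks=dynamic,
        planted_k=len(set(lay.dynamic.values())) if lay.dynamic else 0,
        motif_disrupting_variants=disrupting,
        expressing_fraction_truth=truth_frac,
    )
    return matrix, expression, truth


# ---------------------------------------------------------------------------
# Genome-side generation


def _make_sequences(config: SimConfig, seed: int, lay: _Layout) -> dict[str, str]:
    grng = _rng(seed, "genome")
    seq = grng.integers(0, 4, size=config.genome_length)
    for _, start, cons in lay.motif_sites:
        for o, b in enumerate(cons):
            seq[start + o] = BASES.index(b)
    return {config.chrom: "".join(BASES[b] for b in seq)}


def _make_variants(config: SimConfig, seed: int, lay: _Layout):
    """Variant records with kinds: disrupting / neutral / singleton / long_indel.

    Disrupting variants change one base of a planted motif occurrence;
    neutral ones sit inside peaks away from motifs.  Returns a list of
    (VariantRecord, kind) in a deterministic order.
    """
    vrng = _rng(seed, "variants")
    genome = _make_sequences(config, seed, lay)[config.chrom]
    pops = ("afr", "eas", "eur", "sas")
    occupied = [(s, s + len(c)) for _, s, c in lay.motif_sites]

    def freqs():
        common = vrng.random() < 0.5
        out = {}
        for p in pops:
            if common:
                out[p] = float(np.clip(vrng.beta(2, 5), 0.0, 1.0))
            else:
                out[p] = float(np.clip(vrng.beta(0.3, 80), 0.0, 0.009))
        return out

    records = []
    for k in range(config.n_disrupting_variants):
        pi, start, cons = lay.motif_sites[k % len(lay.motif_sites)]
        off = int(vrng.integers(0, len(cons)))
        ref = cons[off]
        alt = BASES[(BASES.index(ref) + 1 + int(vrng.integers(0, 3))) % 4]
        records.append(
            (
                VariantRecord(config.chrom, start + off + 1, ref, alt,
                              allele_count=2 + int(vrng.poisson(20)), pop_freqs=freqs()),
                "disrupting",
            )
        )

    def random_site():
        while True:
            pi = int(vrng.integers(0, config.n_peaks))
            pk = lay.peaks[pi]
            pos0 = int(vrng.integers(pk.start + 20, pk.end - 20))
            if all(not (s - 12 <= pos0 < e + 12) for s, e in occupied):
                return pos0

    for _ in range(config.n_neutral_variants):
        pos0 = random_site()
        ref = genome[pos0]
        alt = BASES[(BASES.index(ref) + 1 + int(vrng.integers(0, 3))) % 4]
        records.append(
            (
                VariantRecord(config.chrom, pos0 + 1, ref, alt,
                              allele_count=2 + int(vrng.poisson(20)), pop_freqs=freqs()),
                "neutral",
            )
        )
    for _ in range(config.n_singleton_variants):
        pos0 = random_site()
        ref = genome[pos0]
        alt = BASES[(BASES.index(ref) + 2) % 4]
        records.append(
            (VariantRecord(config.chrom, pos0 + 1, ref, alt, allele_count=1, pop_freqs=freqs()),
             "singleton"),
        )
    for _ in range(config.n_long_indel_variants):
        pos0 = random_site()
        ref = genome[pos0 : pos0 + 5]
        records.append(
            (VariantRecord(config.chrom, pos0 + 1, ref, ref[0],
                           allele_count=2 + int(vrng.poisson(5)), pop_freqs=freqs()),
             "long_indel"),
        )
    # credible-set annotations on the first few non-singleton records
    ppa = vrng.dirichlet(np.ones(max(config.n_credible_variants, 1)))
    for i in range(min(config.n_credible_variants, len(records))):
        records[i][0].ppa = float(ppa[i])
    return records


def _consensus_pwm(consensus: str, p_major: float = 0.97) -> PWM:
    w = len(consensus)
    mat = np.full((w, 4), (1.0 - p_major) / 3.0)
    for i, b in enumerate(consensus):
        mat[i, BASES.index(b)] = p_major
    return PWM(name=f"MOTIF_{consensus}", matrix=mat)


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _kmer_weight_table(config: SimConfig, seed: int, genome: str, variants) -> pd.DataFrame:
    """Weights for every 11-mer appearing in any variant's 19-bp windows.

    Weights are standard normal, plus a positive bonus for k-mers carrying a
    planted motif consensus, so that motif-disrupting alleles shift the
    summed score.
    """
    krng = _rng(seed, "kmers")
    k = config.kmer_k
    flank = (19 - 1) // 2
    kmers = set()
    for v, kind in variants:
        if not v.is_snv:
            continue
        pos0 = v.pos - 1
        left = genome[pos0 - flank : pos0]
        right = genome[pos0 + 1 : pos0 + flank + 1]
        for allele in (v.ref, v.alt):
            window = left + allele + right
            for i in range(len(window) - k + 1):
                kmers.add(window[i : i + k])
    kmers = sorted(kmers)
    weights = krng.standard_normal(len(kmers))
    bonus = np.zeros(len(kmers))
    for i, km in enumerate(kmers):
        if any(c in km or c in revcomp(km) for c in config.motif_consensus if len(c) <= k):
            bonus[i] = config.motif_bonus
    return pd.DataFrame({"kmer": kmers, "weight": weights + bonus})


def simulate_genome(config: SimConfig, seed: int):
    """Generate (sequences, PeakSet, promoter table, PWMs, variant records,
    k-mer weight table) consistent with :func:`simulate_cohort` at the same
    (config, seed)."""
    config.validate()
    lay = _layout(config, seed)
    sequences = _make_sequences(config, seed, lay)
    variants = _make_variants(config, seed, lay)
    promoters = lay.genes[["gene", "chrom", "tss", "strand", "biotype"]].copy()
    pwms = [_consensus_pwm(c) for c in config.motif_consensus]
    kmer_table = _kmer_weight_table(config, seed, sequences[config.chrom], variants)
    return sequences, lay.peaks, promoters, pwms, [v for v, _ in variants], kmer_table


def variant_kinds(config: SimConfig, seed: int) -> pd.DataFrame:
    """Table of (variant key, kind) for the planted variant set."""
    lay = _layout(config, seed)
    records = _make_variants(config, seed, lay)
    return pd.DataFrame({"key": [v.key for v, _ in records], "kind": [k for _, k in records]})


# ---------------------------------------------------------------------------
# Temporal archetype profiles (for cluster-number selection)

DEFAULT_ARCHETYPES = np.array(
    [
        [0.80, 0.10, 0.10],
        [0.10, 0.80, 0.10],
        [0.10, 0.10, 0.80],
        [0.45, 0.45, 0.10],
        [0.10, 0.45, 0.45],
    ]
)


def simulate_archetype_profiles(
    n_loci: int = 5000,
    archetypes: np.ndarray | None = None,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Loci-by-timepoint profiles from well-separated unit-sum archetypes.

    Returns (profiles, labels); profiles carry Gaussian noise of sd
    *noise_sd* and are strictly positive (clipped) but not re-normalized —
    row normalization is the clustering step's job.
    """
    if archetypes is None:
        archetypes = DEFAULT_ARCHETYPES
    archetypes = np.asarray(archetypes, dtype=float)
    rng = _rng(seed, "archetypes")
    labels = np.arange(n_loci) % len(archetypes)
    rng.shuffle(labels)
    profiles = archetypes[labels] + rng.normal(0.0, noise_sd, size=(n_loci, archetypes.shape[1]))
    return np.clip(profiles, 1e-6, None), labels
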