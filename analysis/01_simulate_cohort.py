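#!/usr/bin/env python
"""Generate the synthetic study cohort and genome, and write every artifact
to disk in the pipeline's native formats.

Emulates a 3-age-group x 3-donor lung cohort: a peak-by-cell fragment
matrix with heterogeneous library complexity, a gene-by-nucleus UMI matrix,
and a small genome carrying promoters, planted motifs, variants, and an
11-mer weight table.  Downstream drivers read these files back, so the
whole analysis exercises the readers and writers end to end.
"""

import json
from pathlib import Path

from screg import io as sio
from screg.simulate import SimConfig, simulate_cohort, simulate_genome, variant_kinds

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "simdata"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig()
    matrix, expression, truth = simulate_cohort(cfg, SEED)
    sequences, peaks, promoters, pwms, variants, kmers = simulate_genome(cfg, SEED)

    sio.write_peak_matrix(matrix, OUT / "atac.mtx", OUT / "peaks.bed", OUT / "barcodes.tsv")
    import scipy.io

    scipy.io.mmwrite(str(OUT / "rna.mtx"), expression.counts.tocoo(), field="integer")
    expression.meta.to_csv(OUT / "nuclei.tsv", sep="\t", index=False)
    (OUT / "genes.txt").write_text("\n".join(expression.genes) + "\n")
    sio.write_fasta(sequences, OUT / "genome.fa")
    sio.write_promoters(promoters, OUT / "promoters.tsv")
    sio.write_pwms(pwms, OUT / "motifs.meme")
    sio.write_variants(variants, OUT / "variants.tsv")
    sio.write_kmer_weights(kmers, OUT / "kmer_weights.tsv")
    variant_kinds(cfg, SEED).to_csv(OUT / "variant_kinds.tsv", sep="\t", index=False)

    truth_json = {
        "planted_link_pairs": sorted(map(list, truth.planted_link_pairs)),
        "planted_dynamic_peaks": truth.planted_dynamic_peaks,
        "planted_k": truth.planted_k,
        "motif_disrupting_variants": sorted(truth.motif_disrupting_variants),
    }
    (OUT / "truth.json").write_text(json.dumps(truth_json, indent=2))

    print(f"cohort: {matrix.shape[0]} peaks x {matrix.shape[1]} cells, "
          f"{expression.shape[0]} genes x {expression.shape[1]} nuclei")
    print(f"planted: {len(truth.planted_link_pairs)} link pairs, "
          f"{len(truth.planted_dynamic_peaks)} dynamic peaks, "
          f"{len(truth.motif_disrupting_variants)} motif-disrupting variants")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
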