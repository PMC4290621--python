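#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes, under scratch/data/ (regenerable, not part of the results):
  - a toy annotated genome with planted filter outcomes (probe BED,
    transcript table, protein exons, lncRNA reference),
  - a transcript-length population drawn from the three-class mixture,
  - a staged 64-patient clinical cohort with 50 planted stage markers,
  - a knock-down experiment (control + 2 siRNA conditions x 4 replicates)
    with 43 up- and 53 down-planted genes.

Every file is a pure function of SEED; rerunning reproduces it exactly.
"""

import pathlib

import pandas as pd

import lncarray as la
from lncarray import io

SEED = 1
DATA = pathlib.Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    fx = la.gen_genome_fixture(seed=SEED)
    io.write_intervals(fx.transcripts, DATA / "transcripts.tsv", "TSV")
    io.write_probe_mappings(fx.probes, DATA / "probes.bed")
    with open(DATA / "protein_exons.bed", "w") as fh:
        for iv in fx.protein_exons:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\texon\t0\t{iv.strand}\n")
    io.write_intervals(fx.reference, DATA / "reference.tsv", "TSV")
    print(f"toy genome: {len(fx.probes)} probes, {len(fx.transcripts)} transcripts, "
          f"{len(fx.expected_retained)} planted to survive the cascade")

    lengths, labels = la.gen_lengths(la.LengthGenSpec(n=5000), seed=SEED)
    pd.DataFrame({"length_nt": lengths, "true_class": labels}).to_csv(
        DATA / "lengths.tsv", sep="\t", index=False)
    print(f"length population: n={len(lengths)}, range "
          f"{lengths.min()}-{lengths.max()} nt, generative breakpoints 400/2300")

    cohort, planted = la.gen_cohort(la.CohortGenSpec(
        n_patients=64, n_probes=1000, n_informative=50, seed=SEED))
    io.write_cohort(cohort, DATA / "cohort_expr.tsv", DATA / "cohort_meta.tsv")
    planted.to_csv(DATA / "cohort_planted.tsv", sep="\t")
    n_mna = int(cohort.metadata["mycn_amplified"].sum())
    print(f"clinical cohort: {cohort.n_samples} patients ({n_mna} MYCN-amplified), "
          f"{cohort.n_probes} probes, {len(planted)} planted stage markers")

    kd, kd_planted = la.gen_knockdown(n_probes=1000, de_up=43, de_down=53,
                                      seed=SEED)
    io.write_cohort(kd, DATA / "knockdown_expr.tsv", DATA / "knockdown_meta.tsv")
    pd.DataFrame({
        "probe_id": kd_planted["up"] + kd_planted["down"],
        "direction": ["up"] * len(kd_planted["up"])
        + ["down"] * len(kd_planted["down"])}).to_csv(
        DATA / "knockdown_planted.tsv", sep="\t", index=False)
    print(f"knock-down: {kd.n_samples} arrays, 43 up / 53 down planted genes")


if __name__ == "__main__":
    main()
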