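#!/usr/bin/env python
"""Apply the sequential SNP quality filters and report attrition.

Reproducibility >= 0.98, then call rate >= 0.95, then minor-allele
frequency >= 0.02 (the minor-allele threshold is interpreted on the
frequency scale).  Prints per-step attrition and the residual missing-data
percentage; writes the filtered dosage matrix and the report under
results/.
"""

from pathlib import Path

from dunefly.pipeline import stage_filter
from dunefly.popgen import read_dosage_csv

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "data" / "synthetic"
OUT = ROOT / "results"


def main():
    panel = read_dosage_csv(DATA / "genotypes.csv", DATA / "popmap.csv",
                            DATA / "locus_metadata.csv")
    res = stage_filter(panel, OUT)
    report = res["report"]
    print(f"input: {report['n_loci_input']} loci, {report['n_individuals']} individuals")
    for step in report["steps"]:
        print(f"  {step['filter']:<15} >= {step['threshold']:<5} "
              f"removed {step['removed']:>6}, remaining {step['remaining']:>6}")
    print(f"residual missing data: {report['missing_pct']:.2f}%")
    res["panel"].genotypes.to_csv(OUT / "genotypes_filtered.csv",
                                  index_label="individual_id")
    print(f"filtered panel -> {OUT / 'genotypes_filtered.csv'}")


if __name__ == "__main__":
    main()
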