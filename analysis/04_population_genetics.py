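"""Population cytogenetics of the focal sample.

Computes the Hardy-Weinberg worked example from the scored IL us-1 genotype
counts, then simulates a larva table under exact HWE at the four observed
inversion frequencies (19 larvae, 9 female / 10 male) to produce the full
frequency-table layout, the mean autosomal heterozygosity, and the
sex-linkage classification of nucleolar expression.
"""

from pathlib import Path

from cytobarcode import (
    allele_frequency,
    frequency_table,
    hwe_test,
    load_fixture,
    mean_heterozygosity,
    sex_linkage_classify,
    simulate_genotypes,
)
from cytobarcode.simulate import DEFAULT_INVERSION_FREQS, SimConfig

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20220308


def main() -> None:
    counts = load_fixture("il_us1_counts")
    hwe = hwe_test(counts)
    lines = [
        f"il_us1_counts: ss={counts.ss} si={counts.si} ii={counts.ii}",
        f"il_us1_frequency: {allele_frequency(counts):.2f}",
        f"il_us1_chi2: {hwe.chi2:.4f} (df={hwe.df}, p={hwe.p:.4f})",
    ]

    cfg = SimConfig(seed=SEED)
    table = simulate_genotypes(cfg)
    profiles = load_fixture("table1_registry")
    df = frequency_table(table, profiles["S. ustulatum"])

    het = mean_heterozygosity(table)
    expected_het = sum(2 * q * (1 - q) for q in DEFAULT_INVERSION_FREQS.values())
    link = sex_linkage_classify(table)
    lines += [
        f"simulated_mean_heterozygosity: {het:.2f}",
        f"hwe_expected_heterozygosity: {expected_het:.2f}",
        f"nucleolar_linkage: {link.classification} "
        f"(exceptions: {len(link.exceptions)})",
    ]

    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "frequency_table.tsv", sep="\t", index=False)
    (OUT / "popgen_report.txt").write_text("\n".join(lines) + "\n")
    print("\n".join(lines))
    print(f"\nFull frequency table written to {OUT / 'frequency_table.tsv'}; "
          "the simulated sample's heterozygosity sits near the Hardy-Weinberg "
          "expectation for the four observed inversion frequencies.")


if __name__ == "__main__":
    main()
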