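"""Parentage inference on the packaged *Pteris fauriei* genotype table.

Loads the transcribed genotype table (72 multilocus genotypes across 20
taxa), classifies each genotype as parental or hybrid, infers maternal
lineages from chloroplast-nuclear co-occurrence, and prints the headline
bookkeeping plus a few inferred hybrid formulas.
"""

from reticulator import (
    infer_all,
    load_fixture,
    records_from_fixture,
    summarize,
)

fixture = load_fixture()
records = records_from_fixture(fixture)
statuses, matrix, maternal, registry, formulas = infer_all(records)
summary = summarize(records, statuses, formulas)

print(f"genotypes: {summary.total_genotypes} "
      f"({summary.parental_genotypes} parental, "
      f"{summary.hybrid_genotypes} of hybrid origin)")
print(f"parental taxa ({summary.n_parental_taxa}): "
      + ", ".join(summary.parental_taxa))

print("\nhybrid contributions per parental taxon "
      "(as maternal / as paternal / either role):")
for taxon, roles in sorted(summary.hybrids_per_parental_taxon.items(),
                           key=lambda kv: -kv[1]["either"]):
    print(f"  {taxon:32s} {roles['maternal']:3d} / "
          f"{roles['paternal']:3d} / {roles['either']:3d}")

print("\nexample formulas (maternal x paternal):")
for record_id in ("Chao2082", "Chao2478", "Chao2035", "Chao1818"):
    f = next(f for f in formulas if f.record_id == record_id)
    print(f"  {f.taxon:18s} {f.genotype_string or '-':10s} "
          f"cp={f.cp_haplotype or '-':4s} -> {f.formula_string}")

# The counts above are the quantities a field survey would report: how many
# distinct genotypes exist, which are plausible parents (homozygous or
# single-group sexual diploids), and which parental lineages fathered or
# mothered the most hybrid taxa.
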