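"""Allele-trait association mining on the packaged character matrix.

For each morphological/habitat character state the miner reports the
alleles (or lineage groups) carried by *all* samples showing the state
(lenient set) and those additionally absent from every other sample
(strict set) — the "which allele travels with this phenotype" question.
"""

from reticulator import associate_states, load_fixture, records_from_fixture

fixture = load_fixture()
alleles = {
    sid: rec.distinct_alleles("Knox3")
    for rec in records_from_fixture(fixture)
    for sid in rec.sample_ids
    if rec.distinct_alleles("Knox3")
}

print("allele-level associations:")
for row in associate_states(fixture.characters, alleles, granularity="allele"):
    label = ", ".join(sorted(row.strict)) if row.strict else (
        "Except " + ", ".join(sorted(row.complement)) if row.complement
        else "Undetermined")
    print(f"  {row.character:16s} {row.state:22s} -> {label} "
          f"({row.n_state_samples} samples)")

print("\ngroup-level associations:")
for row in associate_states(fixture.characters, alleles, granularity="group"):
    strict = ", ".join(sorted(row.strict)) or "-"
    lenient = ", ".join(sorted(row.lenient)) or "-"
    print(f"  {row.character:16s} {row.state:22s} strict: {strict:6s} "
          f"universal: {lenient}")

# Reading the output: red-brown stipes occur exactly in the D4 carriers;
# triangular costal veins travel with the F lineage group and areolate
# veins with the G group (G strictly — no non-areolate sample carries G).
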