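# Fixture provenance

## table1.tsv

A full transcription of the published genotype table for the *Pteris fauriei*
group: one row per distinct multilocus genotype, each represented by one
voucher sample. 72 rows, 20 taxon names. The published table uses ditto marks
("=" meaning same-as-above) and "–" for missing data; this file ships fully
expanded, with "-" as the single missing-data token and every inherited cell
resolved. Genotype strings keep the "*" unassorted-allele marker verbatim
(e.g. `A1D7*`: a triploid for which only two distinct alleles were observed,
so the exact dosage cannot be asserted).

Columns: `sample_id`, `taxon`, `matches_type` (Y = morphologically identical
to the type specimen), `hybrid_formula` (the parentage reported in the source,
maternal x paternal — informational only, never read by the inference code),
`knox3` / `ibr3` (nuclear genotype strings), `cp_haplotype` (chloroplast
haplotype label; primed labels such as `cf'` and `ca'` are distinct
haplotypes), `ploidy` (2 / 3 / -), `mode` (sex / apo / -), `maternal_knox3` /
`maternal_ibr3` (reported maternal lineages, informational), `region`,
`elevation` (l = ≤1000 m, h = >1000 m, both).

Transcription judgment calls (the source table is typeset with run-together
multi-row cells; each call below is the reading adopted here):

- **Chao2858**: printed as `– = S14V22W23 ca 3X apo D7 W23`. The "=" is read
  as the *Knox3* cell, inheriting `D7F3G1` from the Chao2867 row; the listed
  genotype is the IBR3 cell. Hybrid-formula cell read as "–".
- **Yang191029002**: printed as `= = = – apo G1 S14`. The three ditto marks
  are read as hybrid formula, *Knox3* (`F16G1`) and *IBR3* (`S14Y87`); the
  single "–" is read as the cpDNA cell, leaving ploidy unknown. This keeps
  the row distinct from Chao2478 (which carries `cxx`).
- **Chao2869**: the source prints the haplotype with a typographic apostrophe
  (`ca’`) and lowercase ploidy (`2x`); normalised to `ca'` and `2`.
- **Chao2182**: the reported maternal-lineage cell prints `H1 = H6`; kept
  verbatim as the string `H1=H6` (informational column).
- **Chao2805**: maternal lineage printed `A?` (allele within group A not
  resolvable); kept verbatim.
- Rows whose formula cell prints "–" keep "-" here even where neighbouring
  rows of the same taxon carry a formula (e.g. Chao2483 `D5F3`); the source
  does not extend the formula to those rows and neither do we.
- Sample ids are kept as printed, minus commas (`Kao 03,037` → `Kao 03037`;
  `CRFJ 34,934` → `CRFJ 34934`); internal spaces and periods retained.

## characters.tsv

A morphology/habitat character matrix for the 69 samples with nuclear
genotype data. **This matrix is a reconstruction, not a transcription**: the
source's raw per-specimen morphology scores live in a monographic treatment
that is not packaged here. States were scored from the published
character-to-lineage association claims so that the association miner can be
exercised end to end:

- `stipe_color`: `red_brown` iff the sample carries allele D4, else
  `stramineous_or_green` (published claim: red-brown stipes ⇔ D4).
- `venation`: `areolate` iff the sample carries a G-group allele,
  `triangular` iff it carries an F-group allele and no G-group allele,
  else `free` (published claim: triangular costal veins ⇔ F group, areolate
  ⇔ G group, hybrids carrying both F and G exhibit areolate veins).
- `elevation_range`: `high` iff the sample's distribution includes
  elevations >1000 m (derived directly from the `elevation` column of
  table1.tsv), else `low`.

Treat associations recovered from this matrix as consistency checks of the
mining logic, not as independent biological evidence.
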