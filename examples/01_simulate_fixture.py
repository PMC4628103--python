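"""Build the synthetic study genome and its ChIP/input read libraries.

The fixture plants four repeat families with known ChIP enrichment weights
into a random background chromosome, then draws paired-end 2x300 bp reads:
the input fraction uniformly, the ChIP fraction weighted by the enrichment
factor of the family at each fragment midpoint.
"""

from collections import Counter

from cenrepeat import assemble_genome, default_fixture_specs, simulate_fractions

specs = default_fixture_specs()
fixture = assemble_genome(specs, chrom_length=300_000, seed=1)
input_lib, chip_lib = simulate_fractions(fixture, coverage_input=1.6,
                                         coverage_chip=1.6, seed=2)

print(f"genome: {fixture.total_length:,} bp, {len(fixture.features)} planted features")
for spec in specs:
    print(f"  {spec.family_id:8s} {spec.family_class:10s} unit {spec.unit_length_bp:>5} bp "
          f"x {spec.copy_number:>3} copies, ChIP weight {spec.enrichment_factor}")

print(f"\nlibraries: {len(input_lib)} input pairs, {len(chip_lib)} ChIP pairs")
print("(the ChIP library is larger because enriched loci draw extra fragments)")

for lib in (input_lib, chip_lib):
    counts = Counter(pr.true_family_id for pr in lib.reads)
    total = len(lib.reads)
    shares = {fam: f"{100 * c / total:.1f}%" for fam, c in counts.most_common()}
    print(f"{lib.fraction:>6}: family shares {shares}")

# The per-family chip/input pair ratio estimates the planted weight directly:
ci = Counter(pr.true_family_id for pr in input_lib.reads)
cc = Counter(pr.true_family_id for pr in chip_lib.reads)
print("\nchip/input pair ratio per family (expected = planted weight):")
for spec in specs:
    ratio = cc[spec.family_id] / max(ci[spec.family_id], 1)
    print(f"  {spec.family_id:8s} {ratio:6.1f}  (planted {spec.enrichment_factor})")
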