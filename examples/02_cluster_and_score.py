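"""Cluster pooled reads and score each cluster's ChIP enrichment ratio (ER).

Reads from both fractions are pooled (tagged with their fraction), filtered
for low-complexity sequence, and joined whenever two reads share a dovetail
overlap covering >= 55% of the shorter read at >= 90% identity; clusters are
the connected components.  ER = ChIP reads / input reads per cluster, and
clusters with ER strictly above 2.0 are called enriched.
"""

from cenrepeat import (assemble_genome, cluster_reads, default_fixture_specs,
                       filter_clusters, pool_fractions, qc_filter,
                       score_clusters, select_enriched, simulate_fractions)

fixture = assemble_genome(default_fixture_specs(), 300_000, seed=1)
input_lib, chip_lib = simulate_fractions(fixture, 1.6, 1.6, seed=2)

pooled = qc_filter(pool_fractions(input_lib, chip_lib))
clusters = cluster_reads(pooled, total_reads=len(pooled))
retained, dropped = filter_clusters(clusters, len(pooled), min_proportion=0.0001)
print(f"{len(pooled)} pooled reads -> {len(clusters)} clusters, {len(retained)} retained")

records = score_clusters(retained)
selected, table = select_enriched(records, threshold=2.0)
print(f"{len(selected)} clusters with ER > 2.0\n")

fam = {c.cluster_id: c.majority_family for c in retained}
print("top of the ER table (majority truth label shown for orientation):")
print(f"{'cluster':>8} {'size':>6} {'input':>6} {'chip':>6} {'ER':>7}  family")
for _, row in table.head(8).iterrows():
    cid = row.cluster_id
    print(f"{cid:>8} {row.n_input + row.n_chip:>6} {row.n_input:>6} "
          f"{row.n_chip:>6} {row.ER:>7.1f}  {fam[cid]}")

print("\nThe satellite family (planted ChIP weight 52) tops the table; the")
print("dispersed LINE copies cluster separately, each with ER near 15; the")
print("unenriched rDNA-like satellite stays near ER 1 and is not selected.")
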