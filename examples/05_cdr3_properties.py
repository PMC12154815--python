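"""CDR3 physicochemical properties and property QTLs.

Trims junctions to CDR3, computes nine per-sequence properties, averages
them per sample, and scans the sample means against all common variants
with the same machinery as the gene-usage scan.
"""

from guqtl import (
    compute_properties,
    compute_usage,
    demo_cohort,
    partition_by_mutation,
    property_qtl_scan,
    retain_genes,
    run_scan,
    sample_mean_properties,
)

props = compute_properties("QQYGSSP")
print("properties of CDR3 'QQYGSSP':")
for k, v in props.items():
    print(f"  {k:<10} {v:8.3f}")

genotypes, truth, annotation, out = demo_cohort(seed=1, n_individuals=80)
unmutated, _ = partition_by_mutation(out.repertoire)
usage = retain_genes(compute_usage(unmutated, "V"), min_count=10)
guqtl_scan_res = run_scan(usage, genotypes)

means = sample_mean_properties(unmutated)
scan, leads = property_qtl_scan(means, genotypes,
                                guqtl_sets=guqtl_scan_res.significant_sets())
print("\nper-property lead variants:")
cols = ["property", "significant", "lead_variants", "p", "n_guqtl_genes_at_lead"]
print(leads[cols].to_string(index=False))
# The gene whose germline V suffix is aromatic-rich (WWF) rides on the
# pleiotropic LD block, so CDR3 aromaticity acquires a QTL at that block
# whose lead variant is also a guQTL for the gene itself.
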