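"""Map Tn-seq junction reads into a quality-controlled insertion catalog.

Simulates junction reads (with realistic 1.38% per-base error, so off-by-one
barcode satellites appear), then runs arm detection, satellite collapsing,
k-mer mapping and genic annotation, printing the QC accounting.
"""

import barhem
from barhem import tnseq

config = barhem.SimConfig(n_genes=10, inserts_per_allele_mean=5.0,
                          tnseq_depth_mean=47.0, base_error_rate=0.0138,
                          seed=7)
genome, annotation = barhem.generate_hybrid_genome(config)
truth = barhem.generate_pool(genome, annotation, config)
reads = barhem.simulate_tnseq_reads(truth, genome, config)

layout = tnseq.JunctionLayout(barcode_length=config.barcode_length,
                              barcode_gap=config.junction_gap)
catalog = barhem.build_catalog(reads, genome, annotation,
                               config.transposon_arm, layout)

print(f"{len(reads)} junction reads from {len(truth.insertions)} true insertions")
for stage, n in catalog.qc.items():
    print(f"  {stage}: {n}")
recovered = set(catalog.records.barcode) & set(truth.clones.barcode)
print(f"true barcodes recovered: {len(recovered)}/{len(truth.clones)}")
print(catalog.records.head(3).to_string(index=False))
print("Off-by-one/two tallies are sequencing-error satellites removed by the "
      "dominance rule; every retained record maps one barcode to one genomic "
      "position and its gene/allele.")
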