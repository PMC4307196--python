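"""End-to-end run on a synthetic community: simulate labeled reads,
train and label a model, classify held-out reads, export a Krona
summary.

The community has 4 phyla x 3 orders; each taxon is an order-1 Markov
chain over {a,c,g,t}, with between-phylum compositional distance
controlled by the separation dial. A held-out read is correct when its
predicted phylum matches the taxon it was sampled from; rejected reads
carry no prediction at that rank.
"""

import tempfile
from pathlib import Path

import hyperbin as hb

spec = hb.CommunitySpec(n_phyla=4, orders_per_phylum=3, reads_per_taxon=100,
                        read_length=1000, separation=5.0, seed=1)
taxa = hb.sample_taxa(spec)
train_records, train_lineages = hb.generate_reads(taxa, spec)
print(f"training community: {len(train_records)} reads of "
      f"{spec.read_length} nt from {len(taxa)} taxa")

model = hb.build_model(train_records, train_lineages, k=4, s=8, r=3,
                       training=hb.TrainingConfig(seed=1))
labeled = sum(lab != hb.REJECT for lab in model.node_labels.for_rank("phylum"))
print(f"model: {model.lattice.n_nodes} nodes, {labeled} phylum-labeled "
      f"(purity voting, alpha={model.classifier.alpha})")

held_spec = hb.CommunitySpec(n_phyla=4, orders_per_phylum=3,
                             reads_per_taxon=25, read_length=1000,
                             separation=5.0, seed=2)
held_records, held_lineages = hb.generate_reads(taxa, held_spec)
assignments, skipped = hb.classify_records(held_records, model)

assigned = [a for a in assignments if a.predictions["phylum"] != hb.REJECT]
correct = sum(a.predictions["phylum"] == held_lineages[a.read_id].get("phylum")
              for a in assigned)
print(f"held-out reads: {len(assignments)}; "
      f"rejected at phylum: {len(assignments) - len(assigned)} "
      f"({1 - len(assigned) / len(assignments):.1%})")
print(f"phylum accuracy among assigned: {correct / len(assigned):.3f}")

with tempfile.TemporaryDirectory() as tmp:
    model_path = Path(tmp) / "model.h5"
    hb.save_model(model, model_path)
    print(f"serialized model: {model_path.stat().st_size / 1e6:.2f} MB")
    krona = Path(tmp) / "krona.txt"
    hb.write_krona_text(assignments, krona)
    print("Krona composition lines (count, then the taxon path):")
    for line in krona.read_text().splitlines()[:5]:
        print("  " + line)
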