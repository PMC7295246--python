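"""Generate a synthetic stage-annotated expression study and inspect its truth.

The generator plants ceRNA triples (lncRNA, miRNA, mRNA) that are
differentially expressed and anti-correlated either in all four tumor
stages or in exactly one, alongside decoy database pairs with no signal.
"""

from stagecerna import SimConfig, generate_dataset, write_fixture

config = SimConfig(
    n_lncRNA=60, n_miRNA=30, n_mRNA=100,
    n_samples_per_stage=40,        # per group: normal and stages I-IV
    n_planted_triples=10,
    frac_stage_specific=0.5,       # half the triples active in one stage only
    planted_log2fc=2.0,            # planted shift on the log2 scale
    planted_correlation=-0.6,      # target population Pearson r
    db_decoy_pairs=80,
    seed=1,
)
dataset = generate_dataset(config)

print("expression matrices:", {cls: m.shape for cls, m in dataset.expression.items()})
print("interaction rows:", len(dataset.interactions))
print("planted pairs:", len(dataset.truth.pairs()),
      "(each triple contributes miRNA-lncRNA and miRNA-mRNA)")
for t in dataset.truth.triples[:3]:
    print(f"  triple {t.miRNA} -| {t.lncRNA}, {t.mRNA}  active in stages {t.stages}")
print("prognostic miRNAs:", dataset.truth.prognostic)

paths = write_fixture(dataset, "scratch/example_fixture")
print(f"wrote {len(paths)} files to scratch/example_fixture/")
# The counts above are the ground truth later examples try to recover.
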