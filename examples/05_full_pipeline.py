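"""The whole benchmark in one call: simulate -> optimize -> assign -> grade.

Compares two primers against two databases on the oral mock community
and prints the survival summary plus the per-condition similarity to
theory — the decision table a study would use to pick its sequencing
conditions.
"""

from ampliopt.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    seed=4,
    mock="mock2",
    primers=("V3-V4", "V4"),
    databases={
        "universal": (),
        "gut-centric": ("Porphyromonas gingivalis", "Prevotella intermedia"),
    },
    read_len=300,
    n_pairs=5000,
    replicates=3,
    chimera_rate=0.05,
    rank="genus",
    grid_max_pairs=1000,
)
bundle = run_pipeline(cfg)

print("Survival summary at each primer's best trim cell:")
print(bundle["table1"].to_string(index=False))

print("\nCondition scores (CLR-based, vs theoretical composition):")
for c in bundle["conditions"]:
    grades = "".join(c.grades)
    print(f"  {c.primer:6s} x {c.database:12s} registered {c.registered[0]}/{c.registered[1]}"
          f"  r={c.spearman_r:+.3f}  grades {grades}")
print("\nA registered gap ('×') turns those reads into 'Unassigned' and drags")
print("every other taxon's grade down with it, even where the rank-order")
print("similarity r survives; the universal database tracks theory closely.")
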