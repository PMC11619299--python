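"""Find the trim lengths that maximize non-chimeric read survival.

Evaluates the filter -> merge -> de-bimera emulator in every cell of the
300 bp truncation grid (90..280 bp in steps of 10, both directions) and
reports the winning cell the way a survival-summary table prints it:
trim lengths, implied overlap, and the three survival percentages.
"""

from ampliopt.grid import GridSpec, optimize_trim, table1_report
from ampliopt.mock import theoretical_composition
from ampliopt.refs import amplicon_lengths, default_primer_pairs, extract_amplicon, mock1_members, synthetic_reference_set
from ampliopt.simulate import SimConfig, simulate_pairs

comp = theoretical_composition(mock1_members())
primers = default_primer_pairs()
refs = synthetic_reference_set(list(comp.abundances))

results = []
for name in ("V3-V4", "V3-V5"):  # one mergeable region, one marginal one
    pair = primers[name]
    amplicons = {t: extract_amplicon(refs[t], pair) for t in comp.abundances}
    cfg = SimConfig(seed=2, n_pairs=4000, read_len=300, pair=pair,
                    composition=comp, chimera_rate=0.05)
    reads = simulate_pairs(cfg, amplicons)
    res = optimize_trim(reads, GridSpec.preset(300), primer=name, max_pairs=1000)
    results.append(res)
    s = res.best_stats
    print(f"{name}: best trims fwd={res.best.fwd_trim} rev={res.best.rev_trim} "
          f"-> {s.nonchimeric_pct:.2f}% non-chimeric survival")

print("\nSurvival summary (overlap = fwd + rev - amplicon length):")
print(table1_report(results, amplicon_lengths()).to_string(index=False))
print("\nShort regions merge comfortably; the long V3-V5 region forces trims")
print("deep into the noisy read tails just to reach the 16 bp minimum")
print("overlap, so it loses many more pairs (and on a 250 bp run, where no")
print("trim pair can reach 16 bp at all, its merge rate drops to ~0).")
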