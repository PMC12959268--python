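"""End-to-end analysis of a synthetic saturation-mutagenesis screen.

Simulates the default screen (15 NNK libraries x 92 colonies on 96-well
plates with wild-type and negative controls) with three planted
specificity-switch mutants at position 728 whose activity is redirected
to l-Ala, runs the full pipeline, and checks that the planted position
tops the designability ranking.
"""

import numpy as np

from hamascreen import (
    PlantedSwitch,
    SyntheticConfig,
    analyze_wells,
    recovery_report,
    simulate_screen,
)

N = 19
ala_profile = np.full(N, 1e-4)
ala_profile[0] = 1.0  # panel channel 0 is l-Ala

config = SyntheticConfig(
    seed=7,
    planted_switches=tuple(
        PlantedSwitch(position=728, mut_residue=m, profile=ala_profile)
        for m in "AML"
    ),
)
wells, truth = simulate_screen(config)
print(f"simulated {len(wells)} wells on "
      f"{len({w.plate_id for w in wells})} plates")

result = analyze_wells(wells)
print(f"JSD significance threshold (max over plates): "
      f"{result.global_threshold:.4f}\n")

print("designability ranking (top 5 positions):")
print(f"{'rank':>4} {'pos':>5} {'shell':>7} {'top3 JSD':>9} {'act. entropy':>13}")
for i, s in enumerate(result.positions[:5], start=1):
    print(f"{i:>4} {s.position:>5} {s.shell:>7} {s.top3_mean_jsd:>9.3f} "
          f"{s.activity_entropy:>13.3f}")

report = recovery_report(truth, result)
print(f"\nplanted position 728 ranked: {report.planted_position_ranks[728]}")
for label, true_jsd, est_jsd in report.planted_jsd:
    print(f"  {label}: true JSD {true_jsd:.3f}, estimated {est_jsd:.3f}")
print(f"significant calls among null mutants: "
      f"{report.null_significant_fraction:.1%} of {report.n_null_eligible}")

print("""
The planted switch position should rank first with a top-3 mean JSD near
1; null positions carry only the Dirichlet profile scatter and
measurement noise the generator emulates.""")
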