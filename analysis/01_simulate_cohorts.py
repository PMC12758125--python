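#!/usr/bin/env python
"""Generate the study's synthetic scenarios, one per regime.

Each scenario is an independent pair (triple, for the mediated regime) of
cohorts sharing one genetic architecture: a pQTL cohort with the measured
protein (also the LD reference), a case-control outcome cohort, and —
when a mediator is wired in — a mediator-GWAS cohort.  Summary-level
artifacts (GWAS/pQTL TSVs, fitted weights, LD, ground truth) are written
under scratch/scenarios/<regime>/ — large intermediates; the downstream
stages read them from there and write their small tables to results/.
"""

from pathlib import Path

from ciswas.synthetic_cohort import REGIMES, scenario_config, simulate_scenario, write_scenario

OUT = Path(__file__).resolve().parent.parent / "scratch" / "scenarios"
SEED = 2026
SIZES = dict(n_individuals=8000, n_pqtl=3000, n_variants=60)


def main() -> None:
    for i, regime in enumerate(REGIMES):
        cfg = scenario_config(regime, seed=SEED + i, **SIZES)
        bundle = simulate_scenario(cfg, gene_id=f"{regime}_gene")
        write_scenario(bundle, OUT / regime)
        t = bundle.truth
        print(f"{regime:16s} planted total effect (liability) = "
              f"{t.true_total_effect:+.3f}  "
              f"log-odds scale = {t.true_total_effect_logodds:+.3f}  "
              f"causal variants = {t.causal_variant_ids}")
    print(f"\nwrote {len(REGIMES)} scenarios under {OUT}")


if __name__ == "__main__":
    main()
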