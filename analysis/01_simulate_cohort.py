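"""Generate the synthetic study cohort.

Emulates the study design downstream steps assume: 45 in vitro and 56
in vivo individuals, each with cord blood, cord and five placenta sections;
maternal IGF2/H19 DMR methylation scores drawn from the founder-cell
binomial model (8 founders in vitro vs 10 in vivo, p = 0.1); X-inactivation
scores (p = 0.5) in females; and qPCR Ct tables with the published group
fold-change effects injected.  Writes results/sim/{ratios,cts}.csv plus a
manifest.
"""

from epifounder.pipeline import run_simulate
from epifounder.synthetic_data import CohortConfig

SEED = 7


def main() -> None:
    config = CohortConfig(seed=SEED)
    paths = run_simulate(config, "results/sim")
    print(f"cohort: {config.n_in_vitro} in vitro / {config.n_in_vivo} in vivo "
          f"individuals, founders {config.founders_in_vitro} vs "
          f"{config.founders_in_vivo}, seed {config.seed}")
    for name, path in paths.items():
        print(f"wrote {name}: {path}")


if __name__ == "__main__":
    main()
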