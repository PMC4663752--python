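#!/usr/bin/env python
"""Generate the synthetic study every downstream analysis step consumes.

Writes the genome, fragmented scaffolds, genetic-map truth, F2 genotypes,
array-probe sequences, synteny hints and the truth record under
``results/synthetic/``.
"""

from pathlib import Path

from vigmap.simulate import SimConfig, simulate_study, write_study

OUT = Path("results/synthetic")


def main() -> None:
    cfg = SimConfig(seed=1)
    truth = simulate_study(cfg)
    write_study(truth, OUT)
    print(f"study conditions: {cfg.n_lgs} LGs x {cfg.lg_size / 1e6:.1f} Mb, "
          f"{cfg.n_individuals} F2 plants, markers every "
          f"{cfg.marker_spacing // 1000} kb, {cfg.cm_per_mb} cM/Mb")
    print(f"planted markers: {len(truth.markers)}")
    print(f"scaffolds: {len(truth.scaffolds)} "
          f"({truth.scaffolds.total_bp / 1e6:.2f} Mb)")
    print(f"planted defects: {len(truth.defect_log())}")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
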