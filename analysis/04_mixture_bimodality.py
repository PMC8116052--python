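#!/usr/bin/env python
"""Mixture repertoires against pathogens of unknown evolutionary rate.

Repeated stochastic gradient-ascent optimizations of a 20-component
specificity vector (fixed effective deliberation beta_hat_tilde = 0.2)
against antigens whose divergences are uniform on delta_hat in
(0, 1.6).  The pooled distribution of optimized specificities is
bimodal -- a specific mode at alpha_hat ~ 1 (equilibrium memory for
conserved pathogens) and a cross-reactive mode at alpha_hat ~ 0.5
(non-equilibrium memory covering moderate drift) -- and the usage
curve shows cross-reactive receptors answering more infections per
stored copy.  Writes mixture_* tables under results/.
"""

import argparse
from pathlib import Path

from optimmune import preset
from optimmune.pipeline import run_mixture


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="results")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-steps", type=int, default=2000)
    parser.add_argument("--n-restarts", type=int, default=20)
    args = parser.parse_args()
    Path(args.out).mkdir(parents=True, exist_ok=True)

    cfg = preset("fig3", seed=args.seed, outdir=args.out,
                 n_steps=args.n_steps, n_restarts=args.n_restarts)
    summary = run_mixture(cfg)
    print(f"pooled specificity modes (alpha_hat): {summary['modes']}")
    print(f"cross-reactive mode ~ {summary['low_mode']}, "
          f"specific mode ~ {summary['high_mode']}")


if __name__ == "__main__":
    main()
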