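#!/usr/bin/env python
"""Single-encounter accounting: utility, recognition, dissipation.

Verifies the normalization of the model (a conserved antigen met with
maximal specificity and deliberation at zero cost yields rescaled net
utility 1 - e^-10, i.e. ~1) and maps the per-encounter net utility and
dissipation over distance and deliberation, the ingredients behind the
phase diagram.  Writes results/single_encounter_surface.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from optimmune import AffinityKernel, DeliberationCost, net_utility


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="results")
    parser.add_argument("--alpha-max", type=float, default=4.0)
    parser.add_argument("--beta-max", type=float, default=10.0)
    args = parser.parse_args()
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)

    kernel = AffinityKernel(args.alpha_max, 2.0, args.alpha_max, 1.0)
    no_cost = DeliberationCost("none")
    conserved = net_utility(kernel, 0.0, args.beta_max, no_cost,
                            beta_max=args.beta_max)
    print(f"conserved antigen, alpha_hat=beta_hat=1, no cost: "
          f"U_net = {conserved.u_net:.6f} (exact: 1 - e^-10)")

    cost = DeliberationCost("linear", 0.1)
    rows = []
    for d_hat in np.linspace(0.0, 2.0, 41):        # distance * alpha_max
        for b_hat in np.linspace(0.0, 1.0, 21):
            out = net_utility(kernel, d_hat / args.alpha_max,
                              b_hat * args.beta_max, cost,
                              beta_max=args.beta_max)
            rows.append((d_hat, b_hat, out.p_mem, out.expected_utility,
                         out.k_diss, out.u_net))
    df = pd.DataFrame(rows, columns=["d_hat", "beta_hat", "p_mem",
                                     "expected_utility", "k_diss", "u_net"])
    df.to_csv(outdir / "single_encounter_surface.csv", index=False)
    peak = df.loc[df.k_diss.idxmax()]
    print(f"dissipation peaks at d_hat={peak.d_hat:.2f}, "
          f"beta_hat={peak.beta_hat:.2f} (K={peak.k_diss:.3f}): the "
          f"non-equilibrium zone sits at intermediate drift")


if __name__ == "__main__":
    main()
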