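"""qPCR-style validation: relative enrichment, t-tests and ER concordance.

Each validation target gets a simulated plate of Ct values (4 replicate
antibody/mock pairs); RE = antibody amount / mock amount reconstructed from
the Ct difference.  Targets are tested against an unenriched control with a
two-sample Student's t-test, and the agreement between sequencing-based ER
and qPCR-based RE is summarized by Pearson's r.
"""

import numpy as np

from cenrepeat import compute_re, correlate_er_re, simulate_qpcr
from cenrepeat.qpcr import validate_targets
from cenrepeat.simulate import combine_plates

# Planted truth: five enriched targets with known antibody/mock ratios and
# the ER values their clusters showed in the sequencing arm.
truth = {"satellite": 52.0, "line_a": 15.0, "line_b": 15.0,
         "line_c": 15.0, "ltr": 2.5}
sequencing_er = {"satellite": 49.8, "line_a": 16.2, "line_b": 13.9,
                 "line_c": 15.4, "ltr": 2.7}

plates = [simulate_qpcr(ratio, 1.0, efficiency=1.0, ct_noise_sd=0.15,
                        n_replicates=4, seed=100 + i, target_id=name)
          for i, (name, ratio) in enumerate(truth.items())]
plates.append(simulate_qpcr(1.0, 1.0, efficiency=1.0, ct_noise_sd=0.15,
                            n_replicates=4, seed=99, target_id="control"))
plate = combine_plates(plates)

results = validate_targets(plate, list(truth), "control")
print(f"{'target':>10} {'true':>6} {'RE':>8} {'t':>8} {'p':>10}  signif")
for r in results:
    star = "*" if r.p_value is not None and r.p_value < 0.01 else ""
    print(f"{r.target_id:>10} {truth[r.target_id]:>6.1f} {r.re:>8.1f} "
          f"{r.t_statistic:>8.2f} {r.p_value:>10.2e}  {star}")

conc = correlate_er_re(sequencing_er, {r.target_id: r.re for r in results})
print(f"\nPearson r between sequencing ER and qPCR RE: {conc.r:.2f}")
print("REs recover the planted ratios within replicate noise; every enriched")
print("target is significant against the control at p < 0.01 (n = 4), and the")
print("two assays agree (r close to 1 when both estimate the same weights).")
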