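"""Score the reference compound panel with the six-attribute
desirability sum.

Computes MW, TPSA, H-bond donors and Crippen logP from each structure,
joins the supplied predictor values (logD at pH 7.4, basic pKa), and
prints the desirability score D in [0, 6]: 6.0 means every attribute
sits inside its full-desirability threshold, and each listed violation
marks an attribute on (or beyond) its penalty ramp.
"""

from glucotriage.datasets import reference_descriptors
from glucotriage.mpo import CALIBRATED_CONFIG, mpo_score

for cid, descr in reference_descriptors().items():
    res = mpo_score(descr, CALIBRATED_CONFIG)
    print(f"{cid:<14s} MW {descr.mw:6.1f}  TPSA {descr.tpsa:6.2f}  "
          f"logP {descr.logp:4.2f}  logD {descr.logd74:4.2f}  "
          f"D = {res.rounded_score:.1f}  "
          f"violations: {', '.join(res.violations) or 'none'}")
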