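"""Full pipeline: simulate, split, train with early stopping, evaluate.

Runs the whole pipeline on the synthetic benchmark for the activity-type
taxonomy and prints the evaluation-fold metrics report.
"""

import json

from behavframe import RunConfig, run_pipeline

report = run_pipeline(RunConfig(taxonomy="T2", seed=1))

print("fold assignment:", report["fold_assignment"]["mapping"])
print("leakage audit:", report["leakage_audit"])
print("best boosting round:", report["model"]["best_iteration"],
      "of", report["model"]["rounds_scanned"], "scanned")
print("\nweighted metrics:", json.dumps(report["metrics"]["weighted"], indent=2))
print("averaged OVR AUC:", round(report["metrics"]["auc"]["average"], 3))

# Pose features are class-conditional Gaussian clusters about 4 sigma
# apart, so a well-behaved pipeline recovers the labels almost perfectly:
# expect held-out accuracy around 0.95-1.0 and OVR AUC near 1.0.  The
# leakage audit certifies every training row came from a training-fold
# video.  Early stopping halts after 10 boosting rounds without
# testing-fold improvement and reverts to the best round.
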