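"""Run the complete pipeline on a synthetic study and score it against
the planted truth."""
import json
import warnings

from chromlink import RunConfig, SyntheticConfig, generate_dataset, run_pipeline
from chromlink.evaluate import evaluate_all
from chromlink.synthetic import load_manifest

generate_dataset(SyntheticConfig(seed=1), "example_dataset")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(
        RunConfig(dataset_dir="example_dataset", output_dir="example_out")
    )

print(json.dumps(result.summary, indent=1, sort_keys=True))
scores = evaluate_all(result, load_manifest("example_dataset"))
print("loop diff recovery:", scores["loop_diff"]["gained"])
print("variant loop targets:", scores["variants"]["loop"])
# The summary lists counts per stage (consensus peaks, SEs, loop diff
# classes, shifted windows, assignments); the recovery blocks report
# precision/recall of each stage against the manifest — 1.0 throughout
# on the default noise settings.
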