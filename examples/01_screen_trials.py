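"""Screen a synthetic trial corpus with the four precision predicates.

Builds a 19-record breast-cancer corpus in which one trial is not
recruiting, one is a non-cancer (reconstruction-surgery-like) trial and
one has no drug intervention, then screens it for BRCA1 with the country
filter set to the United States.
"""

import tempfile
from collections import Counter
from pathlib import Path

from oncomatch import neoplasm_subset, parse_mesh_tree, parse_trials, screen
from oncomatch.fixtures import ScenarioSpec, make_mesh_file, make_trial_corpus

with tempfile.TemporaryDirectory() as tmp:
    work = Path(tmp)
    vocab = neoplasm_subset(parse_mesh_tree(make_mesh_file(work / "mesh.txt")))
    spec = ScenarioSpec(
        seed=1,
        n_trials=19,
        defects=((1, "NOT_RECRUITING"), (1, "NOT_CANCER"), (1, "NO_DRUG")),
        gene="BRCA1",
        condition="Breast Neoplasms",
    )
    trials = parse_trials(make_trial_corpus(spec, work / "trials.xml"))
    decisions = [screen(t, "BRCA1", vocab, ["United States"]) for t in trials]

accepted = sum(d.accepted for d in decisions)
reasons = Counter(code for d in decisions if not d.accepted for code in d.reasons)
print(f"trials screened : {len(decisions)}")
print(f"trials accepted : {accepted}")
for code, count in sorted(reasons.items()):
    print(f"rejected due to {code}: {count}")

# 16 of 19 records survive: each injected defect fails exactly one of the
# four predicates (recruiting status, neoplasm MeSH condition, drug
# intervention), and each rejection names its failing predicate.
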