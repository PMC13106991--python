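"""Encode nest records into daily survival histories.

Each nest becomes a chain of Bernoulli outcomes over the transitions
t = 1..26 after laying.  Three mortality scenarios (overall / no-predation /
predation) differ in which fates count as failures versus censorings, and
two dataset variants differ in how dummy-egg-protected nests enter: with
their final fates (all_nests) or cut at the day of human intervention
(natural_only).  The failure counts obey a conservation identity: overall
failures = no-predation failures + predation failures + unknown-cause
deaths.
"""

from ruffnest import ScenarioConfig, encode_dataset, simulate_dataset

nests, _ = simulate_dataset(ScenarioConfig(rng_seed=1))

for variant in ("all_nests", "natural_only"):
    print(f"\nvariant: {variant}")
    fails = {}
    for scenario in ("overall", "no_predation", "predation"):
        histories = encode_dataset(nests, scenario, variant)
        n_fail = sum(h.terminal == "failed" for h in histories)
        n_cens = sum(h.terminal == "censored" for h in histories)
        days = sum(len(h.y) for h in histories)
        fails[scenario] = n_fail
        print(f"  {scenario:13s} {days:5d} exposure days, "
              f"{n_fail:3d} failures, {n_cens:3d} censored")
    unknown = sum(n.fate == "unknown_dead" for n in nests)
    print(f"  conservation: {fails['overall']} = {fails['no_predation']} + "
          f"{fails['predation']} + {unknown} (unknown-cause deaths)")
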