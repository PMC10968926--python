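"""Sensitivity of the ecosystem to one emotion's intensity.

Perturbs the deterministic strategies one at a time by delta = +/-0.1
(positive delta = a more intense emotion) and reports the asymptotic
inhomogeneities.  The interesting case is anger: softening it
(delta=-0.1 gives x=0.30, y=0.40) lets angry agents accept the standard
50% offers, deaths almost cease, and the population stays mixed.
"""

from spatial_ultimatum import Emotion, GameParams, Scenario, run_scenario

print("scenario            <Ip>           <Iq>")
base = run_scenario(Scenario(GameParams(), replicates=5), master_seed=9)
print(f"baseline            {base.Ip_mean:.3f}±{base.Ip_sd:.3f}    "
      f"{base.Iq_mean:.3f}±{base.Iq_sd:.3f}")
for emotion in (Emotion.ANGER, Emotion.FEAR, Emotion.SADNESS):
    for delta in (-0.1, 0.1):
        s = run_scenario(
            Scenario(GameParams(deltas={emotion: delta}), replicates=5),
            master_seed=9,
        )
        label = f"{emotion.value} {delta:+.1f}"
        print(f"{label:<18s}  {s.Ip_mean:.3f}±{s.Ip_sd:.3f}    "
              f"{s.Iq_mean:.3f}±{s.Iq_sd:.3f}")
print()
print("Less anger (or more generous fear) flattens both distributions; the")
print("baseline's inhomogeneity is largely driven by anger's harsh terms,")
print("whose offers and demands sit exactly at the other strategies' margins.")
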