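"""The with/without-ToM safety benchmark at a reduced scale.

Trains the three behaviour-style policies and the theory-of-mind
modules (shortened budgets so the script finishes in a few minutes),
then runs paired randomized episodes with pedestrian 2 reckless, with
and without the ToM bystander, and prints the comparison.  The full
benchmark (1500 policy episodes, 300 ToM episodes, 100 evaluation
episodes per condition) is what `scripts/acceptance.py` runs.
"""

from tomsnn.experiments import compare_conditions, train_full_system

print("training policies and ToM modules (reduced budgets) ...")
system = train_full_system(seed=7, policy_episodes=400, tom_episodes=100)

cmp = compare_conditions("reckless", n=40, seed=11, system=system)
print(f"\npedestrian 2 policy: {cmp.style}   ({cmp.n} paired episodes)")
print(f"  bystander score with ToM:    {cmp.with_tom.mean:.2f} +- {cmp.with_tom.std:.2f}")
print(f"  bystander score without ToM: {cmp.without_tom.mean:.2f} +- {cmp.without_tom.std:.2f}")
print(f"  pedestrian-2 collisions:     {cmp.ped2_collisions_with} with ToM "
      f"vs {cmp.ped2_collisions_without} without")
print(f"  episodes with an intervention: {cmp.help_episodes}")
print()
print("Interventions are deliberately rare: the bystander stops a pedestrian")
print("only when its predicted next cell is already claimed by someone else,")
print("so at this reduced scale a run may see none at all.  Each intervention")
print("costs the bystander 10 score points; the collision it prevents would")
print("have cost the pedestrian 40.")
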