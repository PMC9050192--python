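"""Train a reckless navigation policy with R-STDP and watch it run.

Trains the 588-channel -> 5-action-population decision network for a
few hundred episodes on random 7x7 worlds (reward: fractional progress
toward the goal), then rolls the greedy policy out on a fresh world and
prints the trajectory.  Training here is deliberately short so the
script finishes in about a minute; the benchmark uses 1500 episodes.
"""

import numpy as np

from tomsnn.agents import ShortTermState, TrainingConfig, act, train_decision_module
from tomsnn.gridworld import bfs_distances, generate_environment, observe, step_world

cfg = TrainingConfig(episodes=800, rng_seed=7, epsilon_min=0.1)
net, log = train_decision_module("reckless", cfg, window_length=20)
last = log.reached_goal[-80:].mean()
print(f"trained 800 episodes; goal reach rate over the last 80: {last:.2f}")

world = generate_environment(12345, n_agents=1, styles=["reckless"])
start, goal = world.agents[0].position, world.agents[0].goal
optimal = bfs_distances(world.walls, start)[goal]
print(f"\nfresh world: start {start}, goal {goal}, walls {sorted(world.walls)}")
print(f"shortest path: {optimal} steps")

rng = np.random.default_rng(0)
stp = ShortTermState()
path = [start]
for step in range(30):
    if world.agents[0].done:
        break
    action = act(net, observe(world, 0), rng=rng, stp=stp)
    world, _ = step_world(world, {0: action})
    path.append(world.agents[0].position)
print(f"greedy rollout ({len(path) - 1} steps): {path}")
print()
print("A run close to the shortest path means the network's goal-relative")
print("channels learned the direction map; occasional extra steps come from")
print("the membrane noise that keeps the policy out of deterministic loops.")
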