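"""Detect cohesive modules in a planted-partition interaction network.

Three 8-node blocks are wired densely inside (p = 0.9) and sparsely
between (p = 0.02); greedy cohesiveness growth with size >= 5 and P < 0.05
filters should return exactly those blocks.
"""

from modreg import SimulationConfig, detect_modules, simulate_expression, simulate_network

config = SimulationConfig(seed=3)
_, truth = simulate_expression(config)
network, truth = simulate_network(config, truth)
print(f"network: {network.n_nodes} nodes, {network.n_edges} edges")

modules = detect_modules(network)
planted = [set(v) for v in truth.modules().values()]
for i, m in enumerate(modules, 1):
    jac = max(len(m.members & p) / len(m.members | p) for p in planted)
    print(f"module {i}: size {m.size}, cohesiveness {m.cohesiveness:.2f}, "
          f"P = {m.p_value:.2e}, best Jaccard to a planted block = {jac:.2f}")
print("a Jaccard of 1.0 means the planted block was recovered exactly")
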