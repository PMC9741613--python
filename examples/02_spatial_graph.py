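"""Building and inspecting the spatial neighbour graph.

Shows how the Gaussian kernel turns physical distance into edge weights:
w(u, v) = exp(-d^2 / (2 theta^2)), restricted to each cell's 30 nearest
neighbours, and what the decay coefficient theta does to the weights.
"""

import numpy as np

from spatype import build_spatial_graph, edge_weight

rng = np.random.default_rng(0)
coords = rng.uniform(0, 500, size=(400, 2))  # µm

graph = build_spatial_graph(coords, n_neighbors=30)
print(f"{graph.n_cells} cells, {graph.n_edges} stored edges")
print(f"adaptive decay coefficient theta = {graph.theta:.1f} µm")
print(f"weight at d = theta:     {edge_weight(graph.theta, graph.theta):.5f}  (= e^-1/2)")
print(f"weight at d = 2 theta:   {edge_weight(2 * graph.theta, graph.theta):.5f}  (= e^-2)")

w = graph.adjacency.data
print(f"edge weights: min {w.min():.4f}, median {np.median(w):.4f}, max {w.max():.4f}")
print("Weights fall off smoothly with distance, so nearby cells dominate the")
print("graph convolution while the 30-neighbour budget bounds its support.")
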