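"""Detect overlapping functional modules on a planted benchmark network.

Generates a small confidence-scored PPI network with three planted
modules, runs the full hub-attachment pipeline (seeds -> growth ->
weak-community screen -> merge), and compares the result with the
planted truth.
"""

from hunter.refine import run_pipeline
from hunter.simulate import generate_network, preset

model = preset("easy", seed=1)
net, truth = generate_network(model)
print(f"input network: {net.number_of_vertices()} proteins, "
      f"{net.number_of_edges()} scored interactions")
print(f"planted modules: {[len(m) for m in truth.modules]} proteins each")

clustering, report = run_pipeline(net, seed=1)
print(f"\nstage counts: {report.n_seeds} non-empty seeds "
      f"({report.n_unique_seeds} unique), {report.n_weak} weak communities, "
      f"{report.n_final} final modules")

for i, module in enumerate(clustering.modules, start=1):
    best = max(len(module & m) / len(module | m) for m in truth.modules)
    print(f"module {i}: {len(module)} proteins, "
          f"best Jaccard vs planted truth = {best:.2f}")

# A Jaccard of 1.00 means the detected module is exactly a planted one;
# the q-connected seed stage finds each dense high-confidence core and
# growth/merging adds nothing spurious in this easy regime.
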