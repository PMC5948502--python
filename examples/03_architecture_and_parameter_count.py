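"""Inspect the LiteNet layer graph: shape propagation and parameter ledger.

Prints the length/channel bookkeeping of the basic network on a 1-s input
and compares the conv-only parameter count (PC) against the four 1-D
comparison networks.  PC excludes dense layers and is the model-size metric
that makes LiteNet "lite".
"""

from litenet import build_litenet_basic, compare_pc, count_parameters

spec = build_litenet_basic(input_length=360)
print("basic LiteNet on a 360-sample input:")
for name, kind, shape in spec.shape_trace():
    if kind in ("input", "standard_conv", "maxpool", "concat", "flatten",
                "dense", "softmax") and "/" not in name or name.endswith("concat"):
        pretty = f"{shape[1]}ch x {shape[2]}" if shape[0] == "map" else f"{shape[1]} units"
        print(f"  {name:<14}{kind:<15}{pretty}")

ledger = count_parameters(spec)
print(f"\nPC (conv weights+biases, dense excluded) = {ledger.pc}")
print(f"full parameter total = {ledger.total}")

print("\nmodel-size comparison (input length 360):")
rows = compare_pc(["litenet-basic", "alexnet1d", "googlenet1d",
                   "squeezenet1d", "mobilenets1d"])
for row in sorted(rows, key=lambda r: r["pc"]):
    print(f"  {row['architecture']:<16} PC {row['pc']:>5}   "
          f"total {row['total_params']:>6}")
print("LiteNet's conv body is the smallest of the five.")
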