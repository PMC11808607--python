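"""Audit the reference architecture's trainable-parameter budget.

Builds the 13-row reference layer table, counts parameters two independent
ways — closed-form arithmetic on the table, and enumeration of the
instantiated model's arrays — and prints the per-block breakdown. The two
columns agreeing, block by block, certifies that the declared wiring is the
wiring actually built; the total is the network's entire memory footprint in
trainable values.
"""

from portnet import build_model, count_params_closed_form, introspect_params, portnet_reference

cfg = portnet_reference(num_classes=3, input_size=224)
closed = count_params_closed_form(cfg)
intro = introspect_params(build_model(cfg, seed=0))

print(f"{'block':>5} {'kind':>12} {'Cin':>5} {'Cout':>5} {'closed-form':>12} {'introspect':>12}")
for (i, a), (_, b) in zip(closed.per_block, intro.per_block):
    blk = cfg.blocks[i]
    print(f"{i:>5} {blk.kind:>12} {blk.in_channels:>5} {blk.out_channels:>5} "
          f"{a:>12,} {b:>12,}")
print(f"{'total':>36} {closed.total:>12,} {intro.total:>12,}")
assert closed.per_block == intro.per_block
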