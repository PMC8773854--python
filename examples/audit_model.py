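"""Audit the canonical multibranch models: layer table, parameters, cost.

Prints the per-layer parameter breakdown of the three-branch EEGNet-style
model for a 22-channel, 1125-sample, 4-class input (total 8,908 trainable
parameters) and the worked multiplication counts showing why factorized
1-D temporal + spatial filters are cheap compared with a dense 3-D filter.
"""

from mbeeg import conv_multiplication_count, describe_model, mbeegnet_spec, mbshallow_spec

print(describe_model(mbeegnet_spec(n_channels=22, n_samples=1125, n_classes=4)))

temporal = conv_multiplication_count(10, (8, 1, 1), 100)
spatial = conv_multiplication_count(10, (1, 22, 1), 21)
dense3d = conv_multiplication_count(10, (8, 22, 3), 100)
print(f"temporal 1-D bank : {temporal:>7,} multiplications")
print(f"spatial 1-D bank  : {spatial:>7,} multiplications")
print(f"factorized pair   : {temporal + spatial:>7,} multiplications")
print(f"one 3-D bank      : {dense3d:>7,} multiplications")
print(f"-> the factorized pair costs {dense3d / (temporal + spatial):.0f}x less")

shallow = mbshallow_spec()
total = sum(c for _, _, c in __import__("mbeeg").count_trainable_parameters(shallow).entries)
print(f"\nthree-branch shallow model total: {total:,} parameters")
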