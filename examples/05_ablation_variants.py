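"""Build the seven ablation variants of the network from config flags.

The grid crosses block type (plain conv / ordinary residual / sparse
residual) with skip attention (none / SE / SE-GRU); every variant keeps the
deep-supervision heads.
"""

import numpy as np

from dsrunet.nn.model import ABLATION_VARIANTS, build_dsrunet, variant_config

x = np.random.default_rng(0).normal(size=(2, 1, 1024))
print(f"{'variant':10s} {'block':16s} {'skip':8s} {'params':>8s}  forward")
for name, (block, skip) in ABLATION_VARIANTS.items():
    net = build_dsrunet(variant_config(name, base_channels=8, se_reduction=4),
                        seed=0)
    out = net.forward(x)
    shapes = f"main {tuple(out.main.shape)}, {len(out.aux)} aux heads"
    print(f"{name:10s} {block:16s} {skip:8s} {net.n_parameters():8d}  {shapes}")
print("\nfull inventory of the complete model:")
print(build_dsrunet(variant_config('dsrunet', base_channels=8,
                                   se_reduction=4), seed=0).describe())
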