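"""Unit and parameter accounting for all six architectures at full scale.

For a 91 x 109 x 91 input, print for each model the number of units
entering the fully connected layer and the total parameter count
(batch-norm running statistics included), computed two independent ways:
closed-form arithmetic over the configuration and the literal array sizes
of a built model.  The two must agree exactly.
"""

from triplanar import count_parameters_closed_form, reference_config, verify_counts

print(f"{'model':<12} {'units -> dense':>14} {'total params':>14}  closed == built")
for kind in ("mv2d", "s2d", "conv1d", "conv3d", "conv3d_sep", "m2d"):
    cfg = reference_config(kind)
    ok, closed, built = verify_counts(cfg)
    print(
        f"{kind:<12} {closed.flatten_units:>14,} {closed.total_parameters:>14,}  {ok}"
    )

sep = count_parameters_closed_form(reference_config("conv3d_sep"))
full = count_parameters_closed_form(reference_config("conv3d"))
print(
    f"\nseparable second conv saves {full.total_parameters - sep.total_parameters:,} "
    "parameters (depthwise 3x3x3 without bias + pointwise 1x1x1 with bias)"
)
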