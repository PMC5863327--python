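"""Build the three classifier architectures and audit their parameter budgets.

Model 2 flattens the 32x32x3 tile into a 3072-vector and reads it as TS
time steps of ID features (TS*ID = 3072).  Only ID enters the parameter
total, so sweeping (TS, ID) trades parameters against sequence length:
consecutive configurations differ by exactly 4*42*delta_ID.
"""

from histoclust import (
    TABLE3_TS_ID,
    build_model1,
    build_model2,
    build_model3,
    count_parameters,
    model2_parameter_count,
)

print("Model 1 (CNN):")
print(build_model1().summary())

print("\nModel 2 (stacked LSTM) parameter budget across the (TS, ID) sweep:")
for ts, id_dim in TABLE3_TS_ID:
    built = count_parameters(build_model2(ts, id_dim))
    analytic = model2_parameter_count(ts, id_dim)
    print(f"  TS={ts:4d} ID={id_dim:4d}  built={built}  closed-form={analytic}")

print("\nModel 3 (CNN-LSTM hybrid):")
print(build_model3(ts=32, id_dim=16).summary())
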