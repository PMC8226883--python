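"""Per-layer parameter and MACC ledger of the detector.

The counts profile (per-channel input length 56) is the
parameter-accounting configuration: the shared autoencoder is counted
once, and batch-norm moving statistics are non-trainable.
"""
from p300kit import NetworkConfig, count_parameters

report = count_parameters(NetworkConfig.from_profile("counts"))
print(f"{'layer':22s}{'out':>8s}{'params':>9s}{'trainable':>11s}{'macc':>8s}")
for row in report.to_rows():
    print(f"{row['layer']:22s}{row['output_shape']:>8s}{row['params']:>9d}"
          f"{row['trainable']:>11d}{row['macc']:>8d}")
print(f"\ntotal parameters : {report.total_params}")
print(f"trainable        : {report.trainable_params}")
print(f"frozen           : {report.frozen_params} "
      f"(autoencoder + batch-norm statistics)")
print(f"total MACC       : {report.total_macc} multiply-accumulates per trial")
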