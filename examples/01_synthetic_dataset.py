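"""Generate a synthetic contact-prediction dataset and inspect its signal.

Builds compact self-avoiding chains, derives 8-Angstrom C-beta contact maps,
and attaches profile/coupling feature tensors with a planted contact signal.
"""

import numpy as np

import contactattn as ca

config = ca.SynthConfig(n_proteins=6, L_min=30, L_max=50,
                        signal_to_noise=5.0, seed=42)
items = ca.make_dataset(config)

print(f"{'id':<12}{'L':>4}{'contacts':>10}{'long-range density':>20}")
for record, features, contacts in items:
    d = ca.contact_density(contacts, "long")
    n_contacts = int(contacts.values.sum() // 2)
    print(f"{record.id:<12}{record.length:>4}{n_contacts:>10}"
          f"{(f'{d:.3f}' if d is not None else 'n/a'):>20}")

# the planted signal: the first `signal_channels` coupling channels are
# contacts + noise, the rest pure noise
_, fs, contacts = items[0]
flat = contacts.values.ravel()
for c in (0, config.signal_channels):
    r = np.corrcoef(fs.plm.values[:, :, c].ravel(), flat)[0, 1]
    kind = "signal" if c < config.signal_channels else "noise"
    print(f"channel {c:2d} ({kind}): correlation with contacts r = {r:+.3f}")

print("\nA signal channel tracks the true contact map (r near 1 at high"
      "\nsignal-to-noise); noise channels do not. Long-range densities of a"
      "\nfew percent match what globular proteins show at the 8 A threshold.")
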