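"""Dynamic APD restitution: how the action potential shortens at fast
pacing.

Each basic cycle length (BCL) is paced to steady state; the final
beat's APD is plotted against the preceding diastolic interval (DI).
Restitution is the key determinant of alternans and wave stability, and
matching it (not just the AP shape) is what the four-current model is
built for.
"""

from fourcurrent import builtin_set
from fourcurrent.protocols import dynamic_apd_restitution

for name in ("epi", "lrd"):
    params = builtin_set(name)
    curve = dynamic_apd_restitution(
        params, bcls=[1000, 800, 600, 500, 400, 300, 250])
    print(f"\n{name} set (steady pacing, APD threshold V = 0.1):")
    print("  BCL (ms)   DI (ms)   APD (ms)")
    for bcl, di, apd in zip(curve.bcl, curve.di, curve.value):
        print(f"  {bcl:7.0f} {di:9.1f} {apd:9.1f}")
    if curve.dropped:
        print(f"  lost 1:1 capture at BCL: {curve.dropped}")
    print("  APD grows with DI: the cell recovers more inward current "
          "at long diastole.")
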