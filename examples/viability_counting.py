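"""LIVE/DEAD viability from a two-channel spot field.

Simulates a calcein/ethidium staining of 500 printed cells at 93% true
viability, counts each channel by blob detection and reports the viability
percentage.
"""

from epidrop import imagequant as iq
from epidrop.synth import gen_livedead

live_img, dead_img, truth = gen_livedead(n_cells=500, viability_pct=93.0,
                                         seed=7)
n_live = iq.count_cells(live_img)
n_dead = iq.count_cells(dead_img)
measured = iq.viability(n_live, n_dead)

print(f"true counts    : {truth.parameters['n_live']} live / "
      f"{truth.parameters['n_dead']} dead")
print(f"detected counts: {n_live} live / {n_dead} dead")
print(f"viability      : {measured:.1f} %")
print()
print("Post-printing viability above ~90% indicates the droplet jetting")
print("forces did not harm the cells.")
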