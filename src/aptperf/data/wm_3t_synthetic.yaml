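# Synthetic 3 T white-matter Bloch-McConnell pool set (bmsim.yaml layout).
#
# This is a stand-in compiled from published literature values for healthy
# human white matter at 3 T, used to derive the fluid-suppression factor
# (the WM Z-spectrum intensity at -3.5 ppm) and as the base tissue of the
# digital phantom:
#   - water relaxation: Stanisz et al., MRM 54 (2005), 3 T WM (T1 1.084 s,
#     T2 69 ms)
#   - semisolid MT pool: Stanisz et al. (pool size ~13.9% of water, exchange
#     ~23 1/s, T2 ~10 us, super-Lorentzian line), centered at -2.5 ppm to
#     carry the observed upfield MT asymmetry
#   - amide pool: ~72 mM exchangeable amide protons (f = 0.0065) at +3.5 ppm,
#     k = 30 1/s, T2 = 40 ms (van Zijl & Yadav review values)
#   - relayed-NOE pool at -3.5 ppm: f = 0.005, k = 16 1/s, T2 = 1 ms
#     (aliphatic rNOE, required for a realistic upfield Z value at 3 T)
water_pool:
  f: 1.0
  t1: 1.084
  t2: 0.069

mt_pool:
  f: 0.139
  t1: 1.0
  t2: 1.0e-05
  k: 23.0
  dw: -2.5
  lineshape: SuperLorentzian

cest_pool:
  amide:
    f: 0.0065
    t1: 1.0
    t2: 0.04
    k: 30.0
    dw: 3.5
  rnoe:
    f: 0.005
    t1: 1.3
    t2: 0.001
    k: 16.0
    dw: -3.5
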