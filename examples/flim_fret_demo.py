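"""FLIM-FRET: donor lifetimes → transfer efficiency → distance.

Simulates TCSPC decay histograms for a donor-only population and for a
quenched donor (10.92% true transfer efficiency), fits each decay by
Poisson maximum likelihood, and converts the mean lifetimes into a FRET
efficiency and a donor-acceptor distance via the Förster relation with
R0 = 52.4 Å (EGFP-mCherry).
"""

import numpy as np

from cytofccs import donor_acceptor_distance, roi_fret_analysis, simulate_tcspc

TAU_DONOR = 2.5  # ns, unquenched donor lifetime
E_TRUE = 0.1092  # true transfer efficiency of the quenched population

donors = [simulate_tcspc([(1.0, TAU_DONOR)], 100_000, seed=i) for i in range(5)]
samples = [
    simulate_tcspc([(1.0, TAU_DONOR * (1 - E_TRUE))], 100_000, seed=50 + i)
    for i in range(5)
]

results = roi_fret_analysis(donors, samples)
tau_d = results[0].tau_donor_unquenched
eff = 100 * float(np.mean([r.efficiency for r in results]))
dist = float(np.mean([r.distance for r in results]))

print(f"mean donor-only lifetime: {tau_d:.3f} ns (truth {TAU_DONOR})")
print(f"mean quenched lifetime:   {np.mean([r.tau_da for r in results]):.3f} ns")
print(f"FRET efficiency:          {eff:.2f} % (truth {100 * E_TRUE:.2f} %)")
print(f"donor-acceptor distance:  {dist:.1f} Å")
print(f"anchor: r(E = 0.5) = {donor_acceptor_distance(0.5):.1f} Å = R0")
print("E > 4% (r < ~90 Å) indicates tagged molecules within ~10 nm, i.e. a")
print("bound ligand-receptor complex rather than free co-expression.")
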