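"""Physical constants and unit conversions used throughout the package.

Internal unit conventions:

* concentrations: nM
* lengths: µm (1 µm³ = 1 fl)
* volumes: fl
* correlation lag times and bin widths: µs
* recording durations: s
* TCSPC times: ns
* molecular brightness: counts / molecule / s (peak of the detection profile)
"""

#: Avogadro constant, mol^-1 (2019 SI exact value).
AVOGADRO = 6.02214076e23

#: Molecules per (nM * fl): 1e-9 mol/L * 1e-15 L * N_A.
MOLECULES_PER_NM_FL = 1e-9 * 1e-15 * AVOGADRO  # = 0.602214076


def molecules(concentration_nm: float, volume_fl: float) -> float:
    """Mean number of molecules at `concentration_nm` in `volume_fl`."""
    return concentration_nm * volume_fl * MOLECULES_PER_NM_FL


def concentration_nm(n_molecules: float, volume_fl: float) -> float:
    """Concentration in nM of `n_molecules` in `volume_fl`."""
    if volume_fl <= 0:
        raise ValueError(f"volume must be positive, got {volume_fl}")
    return n_molecules / (volume_fl * MOLECULES_PER_NM_FL)
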