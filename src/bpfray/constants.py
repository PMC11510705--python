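"""Physical constants and unit conventions.

Units used throughout the package: time in ns, length in Å, angles in
degrees, energy in kcal/mol, entropy in eu (cal mol⁻¹ K⁻¹).
"""

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL_PER_MOL_K: float = 1.987204e-3

#: Euler–Mascheroni constant (enters the transition-path-time formula).
EULER_GAMMA: float = 0.5772156649

#: Conversion from kcal mol⁻¹ K⁻¹ to entropy units (cal mol⁻¹ K⁻¹).
EU_PER_KCAL_PER_MOL_K: float = 1000.0


def beta(temperature_k: float) -> float:
    """Inverse thermal energy 1/(kB·T) in mol/kcal."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return 1.0 / (KB_KCAL_PER_MOL_K * temperature_k)
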