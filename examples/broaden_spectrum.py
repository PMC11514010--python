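"""Broaden the emission line of the Ag16 guanine emitter into a band.

The TD-DFT emission of Ag16(G) is a single stick at 1.67 eV with oscillator
strength 1.33.  Gaussian broadening (0.15 eV FWHM) turns it into the smooth
near-IR band one would overlay on a measured fluorescence spectrum; the axis
conversion shows the same curve against wavelength.
"""

from agphot import StickSpectrum, broaden, convert_axis, load_fixture, normalize

d = load_fixture("Ag16(G)")
s1 = d.context("S1-opt").state("S1")
sticks = StickSpectrum(lines=((s1.energy, s1.oscillator_strength),), kind="emission")

sp = broaden(sticks, fwhm=0.15)
print(f"peak: {sp.argmax_position():.3f} eV; integrated intensity "
      f"{sp.integral():.3f} (equals the oscillator strength {s1.oscillator_strength})")

nm = normalize(convert_axis(sp, "nm"), "max")
print(f"on the wavelength axis the peak sits at {nm.argmax_position():.0f} nm "
      "(near-IR), with the maximum normalized to 1 for overlay plots.")
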