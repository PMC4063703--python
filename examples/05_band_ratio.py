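"""Size-normalized RT-PCR band ratios for read-through quantification.

Gel band intensity scales with amplicon length, so band intensities are
divided by their sizes before being expressed relative to an internal
control amplicon (R1): (band/size) / (R1/R1 size).
"""

from termsig.readthrough import BandMeasurement, band_ratio

r1 = BandMeasurement("F-R1", intensity=1200, size_bp=200)   # loading control
r2 = BandMeasurement("F-R2", intensity=450, size_bp=300)    # past terminator
r3 = BandMeasurement("F-R3", intensity=90, size_bp=350)     # further past

for band in (r2, r3):
    print(f"{band.label}: size-normalized ratio to R1 = "
          f"{band_ratio(band, r1):.3f}")
# A ratio near 1 means as much product as the control amplicon (full
# read-through); near 0 means transcription terminated before the amplicon.
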