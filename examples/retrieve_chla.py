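"""Retrieve chlorophyll-a from water-leaving reflectance with every
algorithm the package ships.

A single clear-water spectrum is pushed through OC2 (blue:green polynomial),
OC3 (max-blue variant), the Gilerson-style NIR:red ratio and the Gons05
semi-analytical model; the printed numbers are concentrations in mg m^-3.
The NIR:red algorithms disagree with the OCx pair here because the example
spectrum describes clear water, below their validity range — exactly the
situation the per-algorithm range filters guard against.
"""

from lakealign import band_ratio, default_registry, gilerson_chla, gons_chla, ocx_chla

registry = default_registry()

spectrum = {
    "b443": 0.0074, "b490": 0.0120, "b560": 0.0095,
    "b665": 0.0012, "b708": 0.0008, "b778": 0.0004, "b865": 0.0002,
}

for algorithm in ("oc2", "oc3"):
    x = band_ratio(spectrum, algorithm)
    for sensor in ("olci", "msi"):
        chla = ocx_chla(x, registry.get("initial", sensor, algorithm))
        print(f"{algorithm:8s} {sensor:5s} log-ratio {x:+.4f} -> {chla:6.3f} mg m^-3")

ratio = band_ratio(spectrum, "nir_red")
gil = gilerson_chla(ratio, registry.get("initial", "olci", "gilerson"))
gons = gons_chla(spectrum["b665"], spectrum["b708"], spectrum["b778"],
                 registry.get("initial", "olci", "gons05"))
print(f"gilerson olci  708:665 ratio {ratio:.3f} -> {gil:6.3f} mg m^-3")
print(f"gons05   olci  (semi-analytical)   -> {gons:6.3f} mg m^-3")
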