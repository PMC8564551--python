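# Effective ionic radii of the lanthanoid ions (pm).
# provenance: literature = tabulated effective radius; fitted = divalent value
# from the quadratic radius-vs-Z fit over the six literature divalent radii.
# Note: the trivalent Er radius is sometimes misprinted as 98.0 pm; the value
# consistent with the lanthanide contraction (and with the F-column bond-length
# interpolation, argument ion Pm) is 89.0 pm, used here.
metal,Z,ox,radius_pm,provenance
La,57,2,146,fitted
La,57,3,103.2,literature
Ce,58,2,140,fitted
Ce,58,3,101.0,literature
Pr,59,2,135,fitted
Pr,59,3,99.0,literature
Nd,60,2,129,literature
Nd,60,3,98.3,literature
Pm,61,2,125,fitted
Pm,61,3,97.0,literature
Sm,62,2,122,literature
Sm,62,3,95.8,literature
Eu,63,2,117,literature
Eu,63,3,94.7,literature
Gd,64,2,113,fitted
Gd,64,3,93.5,literature
Tb,65,2,110,fitted
Tb,65,3,92.3,literature
Dy,66,2,107,literature
Dy,66,3,91.2,literature
Ho,67,2,106,fitted
Ho,67,3,90.1,literature
Er,68,2,104,fitted
Er,68,3,89.0,literature
Tm,69,2,103,literature
Tm,69,3,88.0,literature
Yb,70,2,102,literature
Yb,70,3,86.8,literature
Lu,71,2,101,fitted
Lu,71,3,86.1,literature
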