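# Target coordinate bond lengths (pm) between divalent lanthanoid ions and
# coordinating atom types.  Only divalent europium is represented in the
# structural data; every other row is extrapolated from the Eu(2+) row via the
# ionic-radius shift rule with the divalent radii table.
metal,element,length_pm,provenance
La,O,295,interpolated
La,N,304,interpolated
La,P,342,interpolated
Ce,O,289,interpolated
Ce,N,298,interpolated
Ce,P,336,interpolated
Pr,O,284,interpolated
Pr,N,293,interpolated
Pr,P,331,interpolated
Nd,O,278,interpolated
Nd,N,287,interpolated
Nd,P,325,interpolated
Pm,O,274,interpolated
Pm,N,283,interpolated
Pm,P,321,interpolated
Sm,O,271,interpolated
Sm,N,280,interpolated
Sm,P,318,interpolated
Eu,O,266,database
Eu,N,275,database
Eu,P,313,database
Gd,O,262,interpolated
Gd,N,271,interpolated
Gd,P,309,interpolated
Tb,O,259,interpolated
Tb,N,268,interpolated
Tb,P,306,interpolated
Dy,O,256,interpolated
Dy,N,265,interpolated
Dy,P,303,interpolated
Ho,O,255,interpolated
Ho,N,264,interpolated
Ho,P,302,interpolated
Er,O,253,interpolated
Er,N,262,interpolated
Er,P,300,interpolated
Tm,O,252,interpolated
Tm,N,261,interpolated
Tm,P,299,interpolated
Yb,O,251,interpolated
Yb,N,260,interpolated
Yb,P,298,interpolated
Lu,O,250,interpolated
Lu,N,259,interpolated
Lu,P,297,interpolated
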