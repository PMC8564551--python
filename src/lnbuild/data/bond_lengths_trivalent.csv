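# Target coordinate bond lengths (pm) between trivalent lanthanoid ions and
# coordinating atom types: median + MAD over a curated structural database.
# provenance: database = computed directly from structures; interpolated =
# filled from an argument ion via the ionic-radius shift rule
# (argument ions: Eu for O, N, S, Cl, Br; Dy for P and I; Pm for F).
metal,element,length_pm,provenance
La,O,269,database
La,N,280,database
La,S,297,interpolated
La,F,260,interpolated
La,Cl,274,interpolated
La,Br,290,interpolated
La,I,331,interpolated
La,P,304,interpolated
Ce,O,263,database
Ce,N,270,database
Ce,S,296,interpolated
Ce,F,259,interpolated
Ce,Cl,273,interpolated
Ce,Br,289,interpolated
Ce,I,330,interpolated
Ce,P,303,interpolated
Pr,O,262,database
Pr,N,275,database
Pr,S,293,interpolated
Pr,F,256,interpolated
Pr,Cl,270,interpolated
Pr,Br,286,interpolated
Pr,I,327,interpolated
Pr,P,300,interpolated
Nd,O,260,database
Nd,N,268,database
Nd,S,296,database
Nd,F,255,interpolated
Nd,Cl,287,database
Nd,Br,293,database
Nd,I,326,interpolated
Nd,P,299,interpolated
Pm,O,254,database
Pm,N,273,database
Pm,S,314,database
Pm,F,254,database
Pm,Cl,264,database
Pm,Br,283,interpolated
Pm,I,325,interpolated
Pm,P,298,interpolated
Sm,O,253,database
Sm,N,264,database
Sm,S,293,database
Sm,F,253,interpolated
Sm,Cl,283,database
Sm,Br,305,database
Sm,I,324,interpolated
Sm,P,297,interpolated
Eu,O,251,database
Eu,N,265,database
Eu,S,289,database
Eu,F,252,interpolated
Eu,Cl,266,database
Eu,Br,282,database
Eu,I,322,interpolated
Eu,P,296,interpolated
Gd,O,247,database
Gd,N,270,database
Gd,S,288,interpolated
Gd,F,251,interpolated
Gd,Cl,264,database
Gd,Br,282,database
Gd,I,322,interpolated
Gd,P,295,interpolated
Tb,O,248,database
Tb,N,263,database
Tb,S,287,interpolated
Tb,F,249,interpolated
Tb,Cl,273,database
Tb,Br,280,interpolated
Tb,I,320,interpolated
Tb,P,293,interpolated
Dy,O,245,database
Dy,N,266,database
Dy,S,290,database
Dy,F,248,interpolated
Dy,Cl,261,database
Dy,Br,287,database
Dy,I,319,database
Dy,P,292,database
Ho,O,243,database
Ho,N,260,database
Ho,S,300,database
Ho,F,247,interpolated
Ho,Cl,263,database
Ho,Br,277,interpolated
Ho,I,318,interpolated
Ho,P,291,interpolated
Er,O,245,database
Er,N,251,database
Er,S,285,database
Er,F,246,interpolated
Er,Cl,272,database
Er,Br,285,database
Er,I,317,interpolated
Er,P,290,interpolated
Tm,O,242,database
Tm,N,257,database
Tm,S,282,interpolated
Tm,F,245,interpolated
Tm,Cl,259,interpolated
Tm,Br,275,interpolated
Tm,I,316,interpolated
Tm,P,289,interpolated
Yb,O,241,database
Yb,N,260,database
Yb,S,281,interpolated
Yb,F,244,interpolated
Yb,Cl,258,interpolated
Yb,Br,274,interpolated
Yb,I,315,interpolated
Yb,P,288,interpolated
Lu,O,241,database
Lu,N,252,database
Lu,S,280,interpolated
Lu,F,243,interpolated
Lu,Cl,257,interpolated
Lu,Br,273,interpolated
Lu,I,314,interpolated
Lu,P,287,interpolated
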