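# Default currency-metabolite list (one id per line).
# Currency metabolites are ubiquitous cofactor-like compounds that take part
# in a large fraction of reactions without being pathway intermediates;
# leaving them in the graph collapses nearly all shortest paths to <= 3 steps.
# The list is intentionally a config file, not code: the appropriate set is
# database-specific, and compound-specific exceptions exist.  Override with
# --currency / build_network(currency=...).
H2O
H+
ATP
ADP
AMP
NAD+
NADH
NADP+
NADPH
FAD
FADH2
CO2
O2
NH3
Orthophosphate
Diphosphate
CoA
Acetyl-CoA-carrier
H2O2
HCO3-
Sulfate
UDP
UTP
GDP
GTP
CMP
CDP
CTP
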