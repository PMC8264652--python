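"""Classify TLS candidates from their six-marker profiles.

A TLS matures from a CD20+/CXCL13+ aggregate (early), through acquisition
of a CD21+ immature FDC network (primary follicular), to a CD23+ mature FDC
network with a BCL6+/- germinal center (secondary follicular). The
classifier applies these conjunctions to per-marker positivity fractions.
"""

from shapely.geometry import Point

from tlsquant import MarkerProfile, TLSObject, classification_audit

profiles = {
    "early aggregate": {"CD20_aggregate": 0.85, "CXCL13": 0.30, "CD4": 0.02},
    "primary follicle": {"CD20_aggregate": 0.80, "CXCL13": 0.25, "CD4": 0.20,
                         "CD21_network": 0.30},
    "secondary follicle, BCL6-": {"CD20_aggregate": 0.75, "CXCL13": 0.20,
                                  "CD4": 0.25, "CD21_network": 0.30,
                                  "CD23_network": 0.20},
    "secondary follicle, BCL6+": {"CD20_aggregate": 0.75, "CXCL13": 0.20,
                                  "CD4": 0.25, "CD21_network": 0.30,
                                  "CD23_network": 0.20, "BCL6": 0.15},
    "no B-cell aggregate": {"CD20_aggregate": 0.10, "CXCL13": 0.40, "CD4": 0.40},
    "network without T help": {"CD20_aggregate": 0.80, "CXCL13": 0.30,
                               "CD21_network": 0.30},
}

candidates = [
    TLSObject(name, Point(i, 0).buffer(0.15), MarkerProfile(fracs))
    for i, (name, fracs) in enumerate(profiles.items())
]
audit = classification_audit(candidates)
print(audit[["tls_id", "phenotype"]].to_string(index=False))
print("\nProfiles outside the defined marker conjunctions (e.g. an FDC "
      "network without CD4+ T cells) stay UNCLASSIFIED.")
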