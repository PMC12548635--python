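group,specimen_id,microscribe_mm,modality,lower_mm,upper_mm,included
G1,W023,122.82,CT_0.75,121.94,122.96,TRUE
G1,W023,122.82,Original,121.10,123.28,TRUE
G1,W031,113.21,CT_0.75,112.48,113.88,TRUE
G1,W031,113.21,Original,112.14,113.69,TRUE
G1,W096,123.72,CT_0.75,121.73,122.53,FALSE
G1,W096,123.72,Original,121.02,124.44,TRUE
G1,W188,126.28,CT_0.75,125.47,126.45,TRUE
G1,W188,126.28,Original,124.37,127.04,TRUE
G1,W264,116.67,CT_0.75,114.90,117.10,TRUE
G1,W264,116.67,Original,114.84,116.77,TRUE
G1,W281,122.48,CT_0.75,121.34,124.06,TRUE
G1,W281,122.48,Original,121.10,123.83,TRUE
G1,W297,117.16,CT_0.75,116.31,117.61,TRUE
G1,W297,117.16,Original,115.19,118.56,TRUE
G1,W343,132.19,CT_0.75,130.74,131.76,FALSE
G1,W343,132.19,Original,129.66,132.30,TRUE
G1,W451,147.20,CT_0.75,145.64,147.22,TRUE
G1,W451,147.20,Original,143.50,146.34,FALSE
G1,W481,124.82,CT_0.75,122.75,124.33,FALSE
G1,W481,124.82,Original,122.86,125.57,TRUE
G2,W728,145.78,CT_0.60,143.63,146.45,TRUE
G2,W728,145.78,Original,142.77,145.61,FALSE
G2,W728,145.78,CT_0.58,139.83,142.39,FALSE
G2,W781,118.88,CT_0.60,117.55,118.77,FALSE
G2,W781,118.88,Original,116.42,118.91,TRUE
G2,W781,118.88,CT_0.58,114.39,115.13,FALSE
G2,W805,121.29,CT_0.60,120.75,121.89,TRUE
G2,W805,121.29,Original,119.31,121.11,FALSE
G2,W805,121.29,CT_0.58,117.27,118.35,FALSE
G2,W914,117.29,CT_0.60,117.03,117.83,TRUE
G2,W914,117.29,Original,116.19,118.25,TRUE
G2,W914,117.29,CT_0.58,113.71,114.43,FALSE
G2,W955,127.90,CT_0.60,126.98,128.32,TRUE
G2,W955,127.90,Original,126.11,129.51,TRUE
G2,W955,127.90,CT_0.58,123.60,124.42,FALSE
G3,W489,122.07,CT_0.60,124.35,125.57,FALSE
G3,W489,122.07,Original,120.64,123.50,TRUE
G3,W489,122.07,CT_0.58,120.78,122.30,TRUE
G3,W535,118.92,CT_0.60,120.89,122.73,FALSE
G3,W535,118.92,Original,117.23,119.62,TRUE
G3,W535,118.92,CT_0.58,117.54,119.18,TRUE
G3,W614,118.61,CT_0.60,121.34,122.40,FALSE
G3,W614,118.61,Original,115.80,120.69,TRUE
G3,W614,118.61,CT_0.58,118.21,118.75,TRUE
G3,W620,152.67,CT_0.60,155.43,157.31,FALSE
G3,W620,152.67,Original,150.21,153.14,TRUE
G3,W620,152.67,CT_0.58,151.22,152.56,FALSE
G3,W650,141.33,CT_0.60,144.00,146.40,FALSE
G3,W650,141.33,Original,138.68,143.71,TRUE
G3,W650,141.33,CT_0.58,140.60,141.78,TRUE
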