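gene	segment	conserved_pos	cdr1_start	cdr1_end	cdr2_start	cdr2_end
TRBV2	V	285	78	96	144	162
TRBV3-1	V	285	78	96	144	162
TRBV4-1	V	285	78	96	144	162
TRBV4-2	V	285	78	96	144	162
TRBV5-1	V	285	78	96	144	162
TRBV5-4	V	285	78	96	144	162
TRBV5-5	V	285	78	96	144	162
TRBV5-6	V	285	78	96	144	162
TRBV6-1	V	285	78	96	144	162
TRBV6-2	V	285	78	96	144	162
TRBV6-3	V	285	78	96	144	162
TRBV6-4	V	285	78	96	144	162
TRBV7-2	V	285	78	96	144	162
TRBV7-3	V	285	78	96	144	162
TRBV7-6	V	285	78	96	144	162
TRBV7-8	V	285	78	96	144	162
TRBV9	V	285	78	96	144	162
TRBV10-1	V	285	78	96	144	162
TRBV10-3	V	285	78	96	144	162
TRBV11-1	V	285	78	96	144	162
TRBV11-2	V	285	78	96	144	162
TRBV12-1	V	285	78	96	144	162
TRBV12-2	V	285	78	96	144	162
TRBV13	V	285	78	96	144	162
TRBV14	V	285	78	96	144	162
TRBV15	V	285	78	96	144	162
TRBV16	V	285	78	96	144	162
TRBV18	V	285	78	96	144	162
TRBV19	V	285	78	96	144	162
TRBV20-1	V	285	78	96	144	162
TRBV24-1	V	285	78	96	144	162
TRBV25-1	V	285	78	96	144	162
TRBV27	V	285	78	96	144	162
TRBV28	V	285	78	96	144	162
TRBV29-1	V	285	78	96	144	162
TRBV30	V	285	78	96	144	162
TRBV5-8	V	285	78	96	144	162
TRBV7-9	V	285	78	96	144	162
TRBV10-2	V	285	78	96	144	162
TRBV11-3	V	285	78	96	144	162
TRBV23-1	V	285	78	96	144	162
TRBJ1-1	J	26				
TRBJ1-2	J	26				
TRBJ1-3	J	26				
TRBJ1-4	J	26				
TRBJ1-5	J	26				
TRBJ1-6	J	26				
TRBJ2-1	J	26				
TRBJ2-2	J	26				
TRBJ2-3	J	26				
TRBJ2-4	J	26				
TRBJ2-5	J	26				
TRBJ2-6	J	26				
TRBJ2-7	J	26				
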