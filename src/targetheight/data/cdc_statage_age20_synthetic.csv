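# Synthetic stand-in for the CDC 2000 stature-for-age chart, final (240-month) row.
# Female column: Normal(163, 6.4634) quantiles; male column anchored to the
# published male-female differences (12.2 cm at P3, 14.7 cm at P97, linear in height).
Sex,Agemos,P3,P5,P10,P25,P50,P75,P90,P95,P97
1,240,163.0437,164.7254,167.3151,171.6422,176.4500,181.2578,185.5849,188.1746,189.8563
2,240,150.8437,152.3686,154.7168,158.6405,163.0000,167.3595,171.2832,173.6314,175.1563
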