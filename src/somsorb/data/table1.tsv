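# Calculated sorption free energies (kJ/mol) in the dry and hydrated humic-acid
# models with bootstrap errors, their hydrated-dry difference with propagated
# error, and anchored experimental relative sorption free energies.
name	group	dg_dry_calc	dg_dry_err	dg_hyd_calc	dg_hyd_err	ddg_calc	ddg_err	ddg_exp_dry	ddg_exp_hyd
propan-2-ol	alcohol	-36.8	0.5	-15.2	1.1	21.6	1.2	-5.2	-9.0
3-methylbutan-1-ol	alcohol	-45.0	1.8	-18.1	1.1	26.9	2.1	-11.6	-11.3
2-methylpropan-1-ol	alcohol	-41.6	0.8	-16.7	1.9	24.9	2.1	-7.6	-6.5
propan-1-ol	alcohol	-41.4	1.1	-23.5	1.1	17.9	1.6	-8.3	-9.1
pentan-1-ol	alcohol	-46.5	1.1	-20.3	2.4	26.2	2.6	-12.4	-12.7
heptan-1-ol	alcohol	-50.4	1.4	-22.2	1.3	28.2	1.9	-17.8	-16.8
phenol	aromatic	-45.8	3.4	-30.3	1.1	15.5	3.6	-19.8	-22.0
cyclopentanol	alcohol	-40.2	1.7	-16.9	1.4	23.3	2.2	-11.3	-14.1
p-xylene	aromatic	-19.6	2.4	3.6	1.4	23.2	2.8	-5.6	-3.4
benzaldehyde	aromatic	-38.5	1.2	-21.2	0.8	17.3	1.4	-12.0	-14.8
acetophenone	aromatic	-39.2	2.4	-17.1	1.5	22.1	2.8	-17.9	-17.7
2-propanone	ketone	-24.2	1.2	-9.9	1.0	14.3	1.6	-5.2	-4.5
4-methylpentan-2-one	ketone	-32.2	0.8	-5.5	1.2	26.7	1.4	-7.8	-5.5
2-hexanone	ketone	-34.8	1.1	-8.4	1.0	26.4	1.5	-9.9	-7.3
2,4-pentanedione	ketone	-41.1	2.0	-20.0	1.2	21.1	2.3	-10.2	-11.6
isopropylether	ether	-29.9	1.6	-0.1	1.2	29.8	2.0	-1.8	-1.8
dimethyl succinate	ester	-63.6	2.0	-39.9	1.4	23.7	2.4	-19.3	-19.4
1-undecene	alkene	-35.1	2.2	5.9	1.7	41.0	2.8	-11.6	-10.6
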