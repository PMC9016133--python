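# 12 diffusion-encoding directions, electrostatic-repulsion optimized
# (antipodally symmetric energy, 8 restarts; design-matrix condition 1.61).
# One unit vector per row: x y z.
0.3962652491 0.0304564388 0.9176307851
-0.1587689295 -0.4582434268 0.8745315253
-0.0984418426 0.5414075844 0.8349772639
-0.5970966924 0.1029430191 0.7955364698
0.7686128486 -0.4110380060 0.4901857266
0.4615924272 0.7498543164 0.4739735598
0.2705916085 -0.8502604512 0.4514834953
-0.8385438703 -0.3974227970 0.3726919613
0.9194160237 0.2457224292 0.3070743609
-0.3268478196 0.9084891159 0.2604189491
-0.8815611315 0.4193986448 0.2166904431
-0.3807212755 -0.9014985184 0.2057953636
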