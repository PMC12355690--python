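synthon	molecules	type	centroid_distance_A	energy_kcal	percent_of_lattice
1	Que1-Que2	H-bond	8.35	-8.42	21.3
2	Que1-Que2	pi-pi stacking	3.56	-6.97	17.8
3	Que1-Que1/Que2-Que2	offset stacking	6.15	-5.10	13.0
4	Que1-Que2	H-bond	13.664	-4.64	11.8
5	Que1-Im	H-bond	8.59	-3.18	8.1
6	Que2-Im	H-bond	9.67	-2.88	7.3
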