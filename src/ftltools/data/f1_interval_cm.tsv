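accession	location	I1b	I1fg	I2f	420	CEN3	total	p_vs_col
Tsu-0	Tsushima, Japan	6.6	6.3	6.9	14.5	9.4	43.7	<2.00e-16
Hi-0	Hilversum, Netherlands	6.8	6.9	6.9	13.6	9.6	43.8	<2.00e-16
Wil-2	Vilnius, Lithuania	6.1	6.9	6.1	15.9	10.1	45.0	<2.00e-16
Kn-0	Kaunas, Lithuania	7.4	6.6	8.0	15.5	8.7	46.2	<2.00e-16
Ler-0	Gorzow, Poland	6.6	8.2	7.6	12.3	11.9	46.6	<2.00e-16
Ws-0	Vassilyevichy, Belarus	6.7	7.7	10.2	13.0	9.0	46.6	<2.00e-16
No-0	Nossen, Germany	7.4	7.9	6.7	14.1	11.4	47.4	<2.00e-16
Wu-0	Wurzburg, Germany	7.6	6.3	9.5	14.0	11.4	48.8	<2.00e-16
Zu-0	Zurich, Switzerland	7.5	7.1	13.4	12.2	9.9	50.1	0.0438
Po-0	Poppelsdorf, Germany	7.2	7.9	9.1	15.8	10.9	51.0	0.000484
Ct-1	Catania, Italy	7.8	8.7	7.2	15.9	12.1	51.7	9.27e-08
Oy-0	Oystese, Norway	7.7	8.4	8.5	15.7	12.5	52.8	0.969
Rsch-4	Rschew, Russia	7.9	6.8	10.7	15.2	12.4	53.1	0.505
Col-0	Columbia, USA	8.0	8.2	8.8	18.0	11.5	54.5	NA
Sf-2	San Feliu, Spain	8.2	8.8	7.4	18.6	12.3	55.3	0.724
Kas	Kashmir, India	6.9	8.6	13.2	13.8	13.3	55.8	<2.00e-16
Kond	Pugus, Tajikistan	7.1	8.1	15.8	13.7	11.4	56.2	<2.00e-16
Edi-0	Edinburgh, Scotland	8.0	8.0	13.4	13.3	13.6	56.3	<2.00e-16
Bay-0	Bayreuth, Germany	8.6	8.3	11.3	18.6	11.5	58.3	<2.00e-16
Mt-0	Martuba, Libya	9.6	7.8	13.2	20.6	9.6	60.8	<2.00e-16
Sha	Pamiro-Alaya, Tajikistan	7.8	7.5	20.0	7.0	18.6	60.9	0.0012
C24	Columbia, USA	8.8	8.5	18.5	12.1	14.1	61.9	<2.00e-16
Bur-0	Burren, Ireland	6.7	9.1	21.9	14.7	17.8	70.2	<2.00e-16
Cvi-0	Cape Verde Islands	9.1	10.0	11.3	12.6	27.6	70.7	<2.00e-16
Can-0	Las Palmas, Canary Isles	7.8	8.5	22.1	12.4	31.4	82.2	<2.00e-16
Co	Coimbra, Portugal	NA	NA	NA	11.1	13.8	NA	NA
Nw-0	Neuweilnau, Germany	NA	NA	NA	14.7	14.4	NA	NA
Mh-0	Szczecin, Poland	NA	NA	NA	14.9	10.1	NA	NA
Wl-0	Wildbad, Germany	NA	NA	NA	17.0	9.5	NA	NA
Bu-0	Burghaun, Germany	NA	NA	NA	28.9	8.8	NA	NA
CIBC5	Ascot, United Kingdom	NA	NA	NA	13.2	11.3	NA	NA
RRS7	North Liberty, USA	NA	NA	NA	17.2	11.7	NA	NA
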