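dataset	trait	population	bin	step1_label	step1_count	step1_errors	step2	inconclusive
training	eye	AA	brown	brown	31	0	.	0
training	eye	AA	brown	not_blue	12	0	brown:8:0;not_blue:4:0	0
training	eye	SA	brown	brown	21	0	.	0
training	eye	SA	brown	not_blue	6	0	.	0
training	eye	EA	brown	brown	34	0	.	0
training	eye	EA	brown	not_blue	1	0	.	0
training	eye	E	blue	blue	11	0	.	0
training	eye	E	blue	green	2	2	.	0
training	eye	E	blue	not_brown	175	0	blue:37:0;not_brown:138:0	0
training	eye	E	blue	not_blue	7	7	.	0
training	eye	E	green	green	1	0	.	0
training	eye	E	green	blue	1	1	.	0
training	eye	E	green	not_blue	92	0	brown:5:5;not_blue:87:0	0
training	eye	E	green	not_brown	76	0	blue:6:6;not_brown:70:0	0
training	eye	E	brown	brown	2	0	.	0
training	eye	E	brown	not_blue	187	0	brown:24:0;not_blue:163:0	0
training	eye	E	brown	not_brown	1	1	.	0
training	eye	mix	blue	not_brown	10	0	blue:2:0;not_brown:8:0	0
training	eye	mix	blue	not_blue	1	1	.	0
training	eye	mix	green	green	2	0	.	0
training	eye	mix	green	brown	1	1	.	0
training	eye	mix	green	not_blue	10	0	.	0
training	eye	mix	green	not_brown	7	0	blue:1:1;not_brown:6:0	0
training	eye	mix	brown	brown	45	0	.	0
training	eye	mix	brown	not_blue	67	0	brown:14:0;not_blue:53:0	0
test	eye	AA	brown	brown	7	0	.	0
test	eye	AA	brown	not_blue	1	0	brown:1:0	0
test	eye	SA	green	green	1	0	.	0
test	eye	SA	brown	brown	7	0	.	0
test	eye	SA	brown	not_blue	1	0	brown:1:0	0
test	eye	EA	brown	brown	10	0	.	0
test	eye	E	blue	blue	3	0	.	0
test	eye	E	blue	not_brown	46	0	blue:10:0;not_brown:36:0	0
test	eye	E	blue	not_blue	2	2	.	0
test	eye	E	green	green	1	0	.	0
test	eye	E	green	not_blue	21	0	brown:2:2;not_blue:19:0	0
test	eye	E	green	not_brown	16	0	blue:1:1;not_brown:15:0	0
test	eye	E	brown	not_blue	25	0	brown:3:0;not_blue:22:0	0
test	eye	mix	blue	blue	1	0	.	0
test	eye	mix	blue	not_brown	3	0	.	0
test	eye	mix	green	green	2	0	.	0
test	eye	mix	green	not_blue	6	0	.	0
test	eye	mix	brown	brown	24	0	.	0
test	eye	mix	brown	not_blue	35	0	brown:12:0;not_blue:23:0	0
training	skin	AA	dark	not_light	15	0	.	24
training	skin	AA	medium	not_light	1	0	.	3
training	skin	SA	dark	not_dark	1	1	.	4
training	skin	SA	medium	not_dark	2	0	.	19
training	skin	SA	light	.	0	0	.	1
training	skin	EA	light	not_dark	9	0	.	21
training	skin	EA	medium	not_dark	1	0	.	4
training	skin	E	light	light	244	0	.	43
training	skin	E	light	not_dark	268	0	.	0
training	skin	mix	dark	not_light	5	0	.	14
training	skin	mix	dark	not_dark	3	3	.	0
training	skin	mix	medium	not_dark	7	0	.	37
training	skin	mix	medium	not_light	4	0	.	0
training	skin	mix	light	light	11	0	.	33
training	skin	mix	light	not_dark	29	0	.	0
test	skin	AA	dark	not_light	4	0	.	4
test	skin	SA	dark	.	0	0	.	1
test	skin	SA	medium	.	0	0	.	7
test	skin	SA	light	.	0	0	.	1
test	skin	EA	light	not_dark	1	0	.	9
test	skin	E	light	light	60	0	.	7
test	skin	E	light	not_dark	47	0	.	0
test	skin	mix	dark	not_light	1	0	.	4
test	skin	mix	medium	not_dark	4	0	.	14
test	skin	mix	light	light	3	0	.	34
test	skin	mix	light	not_dark	11	0	.	0
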