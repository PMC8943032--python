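theta_deg,radius_mm,height_mm
0.0,4.112118289867883,0.0
22.5,3.4484089859624714,0.0210094916046791
45.0,2.917244371785756,0.05544438074738156
67.5,2.4921548850279995,0.09781045967079949
90.0,2.151957012411706,0.14631859800814864
112.5,1.87969765023509,0.19997400721832773
135.0,1.661809279203379,0.2581233505839061
157.5,1.487433853317914,0.32029694718663343
180.0,1.3478817101321168,0.3861370951299023
202.5,1.2361985382123488,0.455360186768271
225.0,1.1468188224637057,0.5277345689470786
247.5,1.0752884974381303,0.6030666363734435
270.0,1.0180429875882944,0.6811916061013386
292.5,0.972229573532145,0.7619671292065971
315.0,0.9355652322941008,0.8452687112183415
337.5,0.9062228672659851,0.93098633399964
360.0,0.8827402583776025,1.0190219033335435
382.5,0.8639471951846265,1.1092872805284995
405.0,0.8489071616920143,1.201702737383512
427.5,0.8368706668887913,1.2961957246537583
450.0,0.8272378953115752,1.392699877027987
472.5,0.8195288163998328,1.4911541994905364
495.0,0.8133592631003402,1.5915023948359182
517.5,0.8084217876443164,1.6936923024721648
540.0,0.8044703404818705,1.7976754260056191
562.5,0.8013080088780645,1.9034065324098355
585.0,0.7987772041472122,2.0108433094740334
607.5,0.7967518085251986,2.119946071120838
630.0,0.7951308903343706,2.2306775023628207
652.5,0.7938336742483868,2.3430024373284843
675.0,0.7927955160098915,2.4568876650679616
697.5,0.7919646810088451,2.5723017588444006
720.0,0.7912997661881871,2.6892149253989244
742.5,0.7907676368024801,2.8075988712964555
765.0,0.7903417752118892,2.927426683954211
787.5,0.7900009594268341,3.0486727253525316
810.0,0.7897282055511405,3.171312536749972
832.5,0.7895099214223879,3.295322752987381
855.0,0.7893352292727561,3.4206810251812767
877.5,0.7891954236564829,3.5473659507847515
900.0,0.7890835376307926,3.6753570101417314
922.5,0.7889939955717651,3.804634508783555
945.0,0.7889223353238883,3.9351795248199704
967.5,0.7888649858371607,4.066973860863555
990.0,0.7888190892107135,4.2
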