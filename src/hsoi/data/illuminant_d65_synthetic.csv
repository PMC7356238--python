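wavelength_nm,spd
380.0,1.052518e+02
381.0,1.054820e+02
382.0,1.057079e+02
383.0,1.059296e+02
384.0,1.061470e+02
385.0,1.063602e+02
386.0,1.065693e+02
387.0,1.067741e+02
388.0,1.069749e+02
389.0,1.071714e+02
390.0,1.073639e+02
391.0,1.075523e+02
392.0,1.077366e+02
393.0,1.079169e+02
394.0,1.080931e+02
395.0,1.082654e+02
396.0,1.084337e+02
397.0,1.085979e+02
398.0,1.087583e+02
399.0,1.089148e+02
400.0,1.090673e+02
401.0,1.092160e+02
402.0,1.093608e+02
403.0,1.095018e+02
404.0,1.096390e+02
405.0,1.097725e+02
406.0,1.099022e+02
407.0,1.100281e+02
408.0,1.101504e+02
409.0,1.102689e+02
410.0,1.103838e+02
411.0,1.104951e+02
412.0,1.106028e+02
413.0,1.107069e+02
414.0,1.108074e+02
415.0,1.109044e+02
416.0,1.109979e+02
417.0,1.110879e+02
418.0,1.111745e+02
419.0,1.112576e+02
420.0,1.113373e+02
421.0,1.114137e+02
422.0,1.114866e+02
423.0,1.115563e+02
424.0,1.116226e+02
425.0,1.116857e+02
426.0,1.117455e+02
427.0,1.118021e+02
428.0,1.118554e+02
429.0,1.119056e+02
430.0,1.119527e+02
431.0,1.119966e+02
432.0,1.120374e+02
433.0,1.120752e+02
434.0,1.121099e+02
435.0,1.121416e+02
436.0,1.121702e+02
437.0,1.121959e+02
438.0,1.122187e+02
439.0,1.122385e+02
440.0,1.122555e+02
441.0,1.122696e+02
442.0,1.122808e+02
443.0,1.122892e+02
444.0,1.122948e+02
445.0,1.122977e+02
446.0,1.122978e+02
447.0,1.122951e+02
448.0,1.122898e+02
449.0,1.122819e+02
450.0,1.122712e+02
451.0,1.122580e+02
452.0,1.122422e+02
453.0,1.122238e+02
454.0,1.122028e+02
455.0,1.121793e+02
456.0,1.121534e+02
457.0,1.121250e+02
458.0,1.120941e+02
459.0,1.120608e+02
460.0,1.120251e+02
461.0,1.119870e+02
462.0,1.119466e+02
463.0,1.119039e+02
464.0,1.118588e+02
465.0,1.118115e+02
466.0,1.117619e+02
467.0,1.117101e+02
468.0,1.116561e+02
469.0,1.115999e+02
470.0,1.115416e+02
471.0,1.114811e+02
472.0,1.114185e+02
473.0,1.113538e+02
474.0,1.112870e+02
475.0,1.112182e+02
476.0,1.111474e+02
477.0,1.110745e+02
478.0,1.109997e+02
479.0,1.109230e+02
480.0,1.108442e+02
481.0,1.107636e+02
482.0,1.106811e+02
483.0,1.105967e+02
484.0,1.105105e+02
485.0,1.104225e+02
486.0,1.103326e+02
487.0,1.102410e+02
488.0,1.101476e+02
489.0,1.100524e+02
490.0,1.099556e+02
491.0,1.098570e+02
492.0,1.097568e+02
493.0,1.096549e+02
494.0,1.095513e+02
495.0,1.094462e+02
496.0,1.093394e+02
497.0,1.092311e+02
498.0,1.091212e+02
499.0,1.090098e+02
500.0,1.088968e+02
501.0,1.087824e+02
502.0,1.086665e+02
503.0,1.085491e+02
504.0,1.084302e+02
505.0,1.083100e+02
506.0,1.081883e+02
507.0,1.080653e+02
508.0,1.079409e+02
509.0,1.078151e+02
510.0,1.076880e+02
511.0,1.075596e+02
512.0,1.074299e+02
513.0,1.072989e+02
514.0,1.071667e+02
515.0,1.070332e+02
516.0,1.068985e+02
517.0,1.067626e+02
518.0,1.066255e+02
519.0,1.064872e+02
520.0,1.063478e+02
521.0,1.062072e+02
522.0,1.060655e+02
523.0,1.059227e+02
524.0,1.057788e+02
525.0,1.056338e+02
526.0,1.054878e+02
527.0,1.053407e+02
528.0,1.051926e+02
529.0,1.050435e+02
530.0,1.048934e+02
531.0,1.047424e+02
532.0,1.045903e+02
533.0,1.044373e+02
534.0,1.042834e+02
535.0,1.041286e+02
536.0,1.039728e+02
537.0,1.038162e+02
538.0,1.036587e+02
539.0,1.035003e+02
540.0,1.033411e+02
541.0,1.031810e+02
542.0,1.030202e+02
543.0,1.028585e+02
544.0,1.026960e+02
545.0,1.025328e+02
546.0,1.023688e+02
547.0,1.022040e+02
548.0,1.020385e+02
549.0,1.018723e+02
550.0,1.017054e+02
551.0,1.015378e+02
552.0,1.013695e+02
553.0,1.012005e+02
554.0,1.010309e+02
555.0,1.008606e+02
556.0,1.006897e+02
557.0,1.005182e+02
558.0,1.003461e+02
559.0,1.001733e+02
560.0,1.000000e+02
561.0,9.982611e+01
562.0,9.965165e+01
563.0,9.947664e+01
564.0,9.930110e+01
565.0,9.912503e+01
566.0,9.894844e+01
567.0,9.877135e+01
568.0,9.859376e+01
569.0,9.841569e+01
570.0,9.823715e+01
571.0,9.805815e+01
572.0,9.787870e+01
573.0,9.769880e+01
574.0,9.751848e+01
575.0,9.733774e+01
576.0,9.715659e+01
577.0,9.697504e+01
578.0,9.679310e+01
579.0,9.661078e+01
580.0,9.642809e+01
581.0,9.624504e+01
582.0,9.606165e+01
583.0,9.587791e+01
584.0,9.569384e+01
585.0,9.550945e+01
586.0,9.532474e+01
587.0,9.513973e+01
588.0,9.495443e+01
589.0,9.476884e+01
590.0,9.458298e+01
591.0,9.439685e+01
592.0,9.421046e+01
593.0,9.402381e+01
594.0,9.383693e+01
595.0,9.364981e+01
596.0,9.346246e+01
597.0,9.327490e+01
598.0,9.308713e+01
599.0,9.289916e+01
600.0,9.271099e+01
601.0,9.252264e+01
602.0,9.233411e+01
603.0,9.214541e+01
604.0,9.195655e+01
605.0,9.176753e+01
606.0,9.157837e+01
607.0,9.138906e+01
608.0,9.119962e+01
609.0,9.101006e+01
610.0,9.082037e+01
611.0,9.063058e+01
612.0,9.044068e+01
613.0,9.025068e+01
614.0,9.006059e+01
615.0,8.987042e+01
616.0,8.968017e+01
617.0,8.948985e+01
618.0,8.929946e+01
619.0,8.910901e+01
620.0,8.891852e+01
621.0,8.872797e+01
622.0,8.853739e+01
623.0,8.834677e+01
624.0,8.815613e+01
625.0,8.796547e+01
626.0,8.777478e+01
627.0,8.758409e+01
628.0,8.739340e+01
629.0,8.720271e+01
630.0,8.701202e+01
631.0,8.682135e+01
632.0,8.663069e+01
633.0,8.644006e+01
634.0,8.624946e+01
635.0,8.605889e+01
636.0,8.586836e+01
637.0,8.567788e+01
638.0,8.548744e+01
639.0,8.529706e+01
640.0,8.510674e+01
641.0,8.491649e+01
642.0,8.472631e+01
643.0,8.453619e+01
644.0,8.434616e+01
645.0,8.415621e+01
646.0,8.396635e+01
647.0,8.377659e+01
648.0,8.358692e+01
649.0,8.339735e+01
650.0,8.320789e+01
651.0,8.301854e+01
652.0,8.282930e+01
653.0,8.264018e+01
654.0,8.245119e+01
655.0,8.226232e+01
656.0,8.207358e+01
657.0,8.188498e+01
658.0,8.169652e+01
659.0,8.150820e+01
660.0,8.132003e+01
661.0,8.113200e+01
662.0,8.094414e+01
663.0,8.075643e+01
664.0,8.056888e+01
665.0,8.038149e+01
666.0,8.019428e+01
667.0,8.000724e+01
668.0,7.982037e+01
669.0,7.963368e+01
670.0,7.944718e+01
671.0,7.926086e+01
672.0,7.907472e+01
673.0,7.888878e+01
674.0,7.870304e+01
675.0,7.851749e+01
676.0,7.833215e+01
677.0,7.814701e+01
678.0,7.796207e+01
679.0,7.777735e+01
680.0,7.759284e+01
681.0,7.740854e+01
682.0,7.722447e+01
683.0,7.704061e+01
684.0,7.685698e+01
685.0,7.667358e+01
686.0,7.649040e+01
687.0,7.630746e+01
688.0,7.612475e+01
689.0,7.594228e+01
690.0,7.576005e+01
691.0,7.557806e+01
692.0,7.539632e+01
693.0,7.521482e+01
694.0,7.503357e+01
695.0,7.485257e+01
696.0,7.467183e+01
697.0,7.449134e+01
698.0,7.431111e+01
699.0,7.413114e+01
700.0,7.395143e+01
701.0,7.377198e+01
702.0,7.359281e+01
703.0,7.341390e+01
704.0,7.323526e+01
705.0,7.305689e+01
706.0,7.287880e+01
707.0,7.270098e+01
708.0,7.252344e+01
709.0,7.234618e+01
710.0,7.216920e+01
711.0,7.199251e+01
712.0,7.181610e+01
713.0,7.163997e+01
714.0,7.146414e+01
715.0,7.128859e+01
716.0,7.111334e+01
717.0,7.093838e+01
718.0,7.076371e+01
719.0,7.058934e+01
720.0,7.041526e+01
721.0,7.024149e+01
722.0,7.006801e+01
723.0,6.989484e+01
724.0,6.972197e+01
725.0,6.954940e+01
726.0,6.937714e+01
727.0,6.920519e+01
728.0,6.903354e+01
729.0,6.886221e+01
730.0,6.869118e+01
731.0,6.852047e+01
732.0,6.835007e+01
733.0,6.817998e+01
734.0,6.801021e+01
735.0,6.784076e+01
736.0,6.767162e+01
737.0,6.750280e+01
738.0,6.733430e+01
739.0,6.716612e+01
740.0,6.699826e+01
741.0,6.683073e+01
742.0,6.666351e+01
743.0,6.649662e+01
744.0,6.633006e+01
745.0,6.616382e+01
746.0,6.599791e+01
747.0,6.583233e+01
748.0,6.566707e+01
749.0,6.550214e+01
750.0,6.533755e+01
751.0,6.517328e+01
752.0,6.500934e+01
753.0,6.484574e+01
754.0,6.468247e+01
755.0,6.451953e+01
756.0,6.435693e+01
757.0,6.419466e+01
758.0,6.403272e+01
759.0,6.387112e+01
760.0,6.370986e+01
761.0,6.354893e+01
762.0,6.338834e+01
763.0,6.322809e+01
764.0,6.306818e+01
765.0,6.290860e+01
766.0,6.274937e+01
767.0,6.259047e+01
768.0,6.243191e+01
769.0,6.227370e+01
770.0,6.211582e+01
771.0,6.195829e+01
772.0,6.180110e+01
773.0,6.164424e+01
774.0,6.148774e+01
775.0,6.133157e+01
776.0,6.117575e+01
777.0,6.102027e+01
778.0,6.086513e+01
779.0,6.071033e+01
780.0,6.055588e+01
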